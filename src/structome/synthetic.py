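"""Synthetic spherocylinder cells with analytic ground truth.

Rod-shaped bacteria are idealised as straight spherocylinders (a cylinder
capped by two hemispheres) with circular cross-sections, a concentric
envelope (outer membrane, periplasm, plasma membrane) and cytoplasmic
ribosomes placed homogeneously.  The closed forms

    V(r, L) = pi r^2 (L - 2r) + (4/3) pi r^3        (volume)
    S(r, L) = 2 pi r (L - 2r) + 4 pi r^2 = 2 pi r L (surface)

give exact ground truth, so every downstream estimator can be validated
without microscope data.  :func:`slice_model` emulates serial ultrathin
sectioning: sections are evaluated at their mid-planes, and optional
multiplicative lognormal noise emulates tracing error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .stereology import CellProfile, SectionMeasurement, SectionStack

__all__ = [
    "SpherocylinderModel",
    "SectionGeometry",
    "cross_section",
    "slice_model",
    "place_ribosomes",
    "analytic_truth",
    "simulate_cell",
]


def spherocylinder_volume(r: float, length: float) -> float:
    """Volume of a spherocylinder of radius ``r`` and pole-to-pole ``length``."""
    return math.pi * r * r * (length - 2 * r) + 4.0 / 3.0 * math.pi * r ** 3


def spherocylinder_surface(r: float, length: float) -> float:
    """Surface area: cylinder wall plus two hemispherical caps (= 2 pi r L)."""
    return 2 * math.pi * r * (length - 2 * r) + 4 * math.pi * r * r


@dataclass(frozen=True)
class SpherocylinderModel:
    """Ground-truth cell geometry (lengths in micrometres).

    ``radius_om`` and ``length_om`` describe the outer surface of the outer
    membrane; ``envelope_width`` is the radial distance from the OM outer
    surface to the PM outer surface (OM thickness + periplasm width), so the
    cytoplasm-bounding (PM) spherocylinder has radius
    ``radius_om - envelope_width`` and length ``length_om - 2*envelope_width``.
    ``ribosome_density_true`` is the homogeneous count per 0.1 fl cytoplasm.

    Defaults emulate an average rod of the measured population: diameter
    0.58 um, length 3.54 um, PM diameter 0.55 um, density 1170 per 0.1 fl.
    """

    cell_id: str = "synthetic"
    radius_om: float = 0.29
    length_om: float = 3.54
    envelope_width: float = 0.015
    pm_thickness: float = 0.006
    om_thickness: float = 0.002
    ribosome_density_true: float = 1170.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.envelope_width + self.pm_thickness > 0:
            raise ValueError("envelope_width + pm_thickness must be > 0")
        if not self.radius_om > self.envelope_width + self.pm_thickness:
            raise ValueError(
                "radius_om must exceed envelope_width + pm_thickness "
                f"({self.radius_om} <= {self.envelope_width + self.pm_thickness})"
            )
        if self.length_om < 2 * self.radius_om:
            raise ValueError("length_om must be >= 2 * radius_om")
        if self.om_thickness < 0 or self.pm_thickness < 0:
            raise ValueError("membrane thicknesses must be >= 0")
        if self.om_thickness > self.envelope_width:
            raise ValueError("om_thickness cannot exceed envelope_width")
        if self.ribosome_density_true < 0:
            raise ValueError("ribosome_density_true must be >= 0")

    @property
    def radius_pm(self) -> float:
        """Outer radius of the PM (cytoplasm-bounding) spherocylinder."""
        return self.radius_om - self.envelope_width

    @property
    def length_pm(self) -> float:
        return self.length_om - 2 * self.envelope_width

    @property
    def cytoplasm_volume(self) -> float:
        """Volume enclosed by the PM trace, in fl."""
        return spherocylinder_volume(self.radius_pm, self.length_pm)


@dataclass(frozen=True)
class SectionGeometry:
    """Noise-free cross-section of the model at one axial position.

    Radii (``r_om``, ``r_pm``), perimeters (``p = 2 pi r``) and areas
    (``a = pi r^2``) of the OM and PM circles; all zero outside the cell.
    """

    axial_position: float
    r_om: float
    r_pm: float
    p_om: float
    p_pm: float
    a_om: float
    a_pm: float


def _radius_at(z: float, radius: float, z_lo: float, z_hi: float) -> float:
    """Cross-section radius of a spherocylinder spanning [z_lo, z_hi]."""
    if z < z_lo or z > z_hi:
        return 0.0
    c_lo, c_hi = z_lo + radius, z_hi - radius
    if z < c_lo:
        d = c_lo - z
    elif z > c_hi:
        d = z - c_hi
    else:
        return radius
    return math.sqrt(max(radius * radius - d * d, 0.0))


def cross_section(model: SpherocylinderModel, z: float) -> SectionGeometry:
    """Analytic cross-section at axial position ``z`` (um from one pole).

    Within the cylindrical mid-segment the radii are constant; within a cap
    they follow the sphere (``r(d) = sqrt(r^2 - d^2)`` at axial distance
    ``d`` from the cap centre).  Both caps share their centres (the PM
    spherocylinder is inset by ``envelope_width`` on every side), so the PM
    radius uses the same construction.
    """
    if not math.isfinite(z):
        raise ValueError(f"axial position must be finite, got {z}")
    r_om = _radius_at(z, model.radius_om, 0.0, model.length_om)
    r_pm = _radius_at(z, model.radius_pm, model.envelope_width,
                      model.length_om - model.envelope_width)
    return SectionGeometry(
        axial_position=z,
        r_om=r_om, r_pm=r_pm,
        p_om=2 * math.pi * r_om, p_pm=2 * math.pi * r_pm,
        a_om=math.pi * r_om * r_om, a_pm=math.pi * r_pm * r_pm,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    # lognormal with mean exactly 1 and coefficient of variation cv
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def slice_model(model: SpherocylinderModel, thickness: float = 0.040,
                offset: float = 0.0, noise_cv: float = 0.0,
                seed: int | None = None) -> SectionStack:
    """Slice the model into a serial-section measurement stack.

    Section slabs are ``[offset + k*t, offset + (k+1)*t]``; every slab
    intersecting the cell produces one measurement, evaluated at the slab
    mid-plane.  Minor and major axes are both the circular diameter (the
    model is straight with circular cross-sections).  With ``noise_cv > 0``
    every perimeter, area and axis is multiplied by an independent lognormal
    factor of unit mean and the given coefficient of variation; PM values
    are then clamped to their OM counterparts so the measurement-ordering
    invariant (PM inside OM) survives the noise.
    """
    if not thickness > 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    if not 0 <= offset < thickness:
        raise ValueError(f"offset must lie in [0, thickness), got {offset}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")

    k_first = -1 if offset > 0 else 0
    k_last = math.ceil((model.length_om - offset) / thickness) - 1
    rng = np.random.default_rng(seed) if noise_cv > 0 else None

    sections: list[SectionMeasurement] = []
    for i, k in enumerate(range(k_first, k_last + 1), start=1):
        geom = cross_section(model, offset + (k + 0.5) * thickness)
        p_om, p_pm = geom.p_om, geom.p_pm
        a_om, a_pm = geom.a_om, geom.a_pm
        d_om, d_pm = 2 * geom.r_om, 2 * geom.r_pm
        minor_om = major_om = d_om
        minor_pm = major_pm = d_pm
        if rng is not None:
            f = _lognormal_factors(rng, noise_cv, 8)
            p_om, a_om, minor_om, major_om = p_om * f[0], a_om * f[1], d_om * f[2], d_om * f[3]
            p_pm = min(p_pm * f[4], p_om)
            a_pm = min(a_pm * f[5], a_om)
            minor_pm = min(d_pm * f[6], minor_om)
            major_pm = min(d_pm * f[7], major_om)
        sections.append(SectionMeasurement(
            section_index=i,
            p_om=p_om, p_pm=p_pm, a_om=a_om, a_pm=a_pm,
            minor_om=minor_om, major_om=major_om,
            minor_pm=minor_pm, major_pm=major_pm,
            ribosomes=0,
            om_thickness_nm=model.om_thickness * 1e3,
            pm_thickness_nm=model.pm_thickness * 1e3,
        ))
    return SectionStack(cell_id=model.cell_id, thickness=thickness,
                        sections=sections, supplied_length=model.length_om)


def _cap_volume(r: float, h: float) -> float:
    """Volume of a spherical cap of height ``h`` on a sphere of radius ``r``."""
    h = min(max(h, 0.0), r)
    return math.pi * h * h * (3 * r - h) / 3.0


def _cytoplasm_below(model: SpherocylinderModel, z: float) -> float:
    """Cytoplasm (PM-enclosed) volume below the plane at axial position z."""
    rp = model.radius_pm
    z_lo = model.envelope_width
    z_hi = model.length_om - model.envelope_width
    z = min(max(z, z_lo), z_hi)
    c_lo, c_hi = z_lo + rp, z_hi - rp
    v = _cap_volume(rp, z - z_lo)            # bottom cap (possibly partial)
    if z > c_lo:
        v += math.pi * rp * rp * (min(z, c_hi) - c_lo)
    if z > c_hi:
        v += 2.0 / 3.0 * math.pi * rp ** 3 - _cap_volume(rp, z_hi - z)
    return v


def place_ribosomes(model: SpherocylinderModel, stack: SectionStack,
                    seed: int | None = None, offset: float = 0.0) -> SectionStack:
    """Fill per-section ribosome counts for a stack sliced from ``model``.

    The whole-cell total is Poisson with mean
    ``density_true * cytoplasm_volume / 0.1`` and is apportioned across
    sections multinomially, with probabilities proportional to each slab's
    cytoplasmic volume (equivalent to independent Poisson counts per slab,
    i.e. homogeneously placed ribosomes).  Counts sum to the drawn total
    exactly.  ``offset`` must match the value given to :func:`slice_model`
    so the slab grid lines up.
    """
    rng = np.random.default_rng(seed)
    t = stack.thickness
    n = stack.n_sections
    start = offset - t if offset > 0 else 0.0  # first slab edge, as sliced
    if start + n * t < model.length_om - 1e-9:
        raise ValueError("stack does not cover the model length")
    edges = start + np.arange(n + 1) * t

    vols = np.array([
        _cytoplasm_below(model, edges[k + 1]) - _cytoplasm_below(model, edges[k])
        for k in range(n)
    ])
    vols = np.clip(vols, 0.0, None)
    total_mean = model.ribosome_density_true * model.cytoplasm_volume / 0.1
    n_total = int(rng.poisson(total_mean))
    if vols.sum() <= 0:
        counts = np.zeros(n, dtype=int)
    else:
        counts = rng.multinomial(n_total, vols / vols.sum())
    new_sections = [replace(s, ribosomes=int(c))
                    for s, c in zip(stack.sections, counts)]
    return SectionStack(cell_id=stack.cell_id, thickness=stack.thickness,
                        sections=new_sections,
                        supplied_length=stack.supplied_length)


def analytic_truth(model: SpherocylinderModel) -> CellProfile:
    """Exact closed-form profile of the model (the recovery-test oracle).

    Membrane shell volumes are the differences between nested spherocylinder
    volumes; the periplasm is the remainder, matching the subtraction
    convention of the measurement pipeline.  ``ribosomes_total`` is the
    expected (non-integer) count at the true density.
    """
    r, L = model.radius_om, model.length_om
    rp, Lp = model.radius_pm, model.length_pm
    vol_whole = spherocylinder_volume(r, L)
    vol_cyt = spherocylinder_volume(rp, Lp)
    vol_om = vol_whole - spherocylinder_volume(r - model.om_thickness,
                                               L - 2 * model.om_thickness)
    vol_pm = vol_cyt - spherocylinder_volume(rp - model.pm_thickness,
                                             Lp - 2 * model.pm_thickness)
    vol_peri = vol_whole - vol_cyt - vol_om - vol_pm
    total = model.ribosome_density_true * vol_cyt / 0.1
    return CellProfile(
        cell_id=model.cell_id,
        n_sections=0,
        length=L,
        diam_om=2 * r,
        diam_pm=2 * rp,
        aspect_ratio=L / (2 * r),
        surf_om=spherocylinder_surface(r, L),
        surf_pm=spherocylinder_surface(rp, Lp),
        vol_whole=vol_whole,
        vol_om=vol_om,
        vol_periplasm=vol_peri,
        vol_pm=vol_pm,
        vol_cytoplasm=vol_cyt,
        ribosomes_total=total,
        ribosome_density=model.ribosome_density_true,
    )


def simulate_cell(model: SpherocylinderModel, thickness: float = 0.040,
                  offset: float = 0.0, noise_cv: float = 0.0,
                  seed: int | None = None) -> SectionStack:
    """Slice the model and place ribosomes in one call.

    ``seed`` (default: the model's own seed) drives both the measurement
    noise and the ribosome placement through independent child streams.
    """
    if seed is None:
        seed = model.seed
    ss = np.random.SeedSequence(seed)
    s_slice, s_ribo = ss.spawn(2)
    stack = slice_model(model, thickness=thickness, offset=offset,
                        noise_cv=noise_cv,
                        seed=int(s_slice.generate_state(1)[0] % (2 ** 31)))
    return place_ribosomes(model, stack, offset=offset,
                           seed=int(s_ribo.generate_state(1)[0] % (2 ** 31)))
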