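"""Per-cell structome profiles from serial-section measurement stacks.

A *structome* profile is the complete quantitative description of one cell
reconstructed from an ordered stack of serial ultrathin sections: length,
outer-membrane (OM) and plasma-membrane (PM) diameters, aspect ratio,
membrane surface areas, compartment volumes (whole cell, OM, periplasm, PM,
cytoplasm), and cytoplasmic ribosome count and density.

Estimators follow the serial-section conventions of quantitative TEM
morphometry:

* length        -- number of sections x section thickness (or an externally
                   supplied value when the stack carries one);
* surface area  -- trapezoid rule over consecutive section perimeters with
                   the section thickness as the height;
* volume        -- Cavalieri-type sum of cross-sectional areas x thickness;
* membrane shell volume -- perimeter x membrane thickness x section height;
* periplasm     -- obtained by subtraction from the whole-cell volume;
* ribosome density -- total count normalised per 0.1 fl of cytoplasm.

All internal computation is carried out at full floating-point precision;
rounding for report tables is applied only by the writers in
:mod:`structome.io`.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Literal

logger = logging.getLogger(__name__)

Boundary = Literal["OM", "PM"]

#: Default section thickness in micrometres (40 nm ultrathin sections).
DEFAULT_THICKNESS_UM = 0.040


@dataclass(frozen=True)
class SectionMeasurement:
    """Morphometry of a single serial section.

    Lengths are in micrometres, areas in square micrometres, membrane
    thicknesses in nanometres.  ``section_index`` is 1-based and strictly
    increasing within a stack.
    """

    section_index: int
    p_om: float = 0.0
    p_pm: float = 0.0
    a_om: float = 0.0
    a_pm: float = 0.0
    minor_om: float = 0.0
    major_om: float = 0.0
    minor_pm: float = 0.0
    major_pm: float = 0.0
    ribosomes: int = 0
    om_thickness_nm: float | None = None
    pm_thickness_nm: float | None = None

    def __post_init__(self) -> None:
        if self.section_index < 1:
            raise ValueError(f"section_index must be >= 1, got {self.section_index}")
        for name in ("p_om", "p_pm", "a_om", "a_pm", "minor_om", "major_om",
                     "minor_pm", "major_pm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.ribosomes < 0:
            raise ValueError(f"ribosomes must be >= 0, got {self.ribosomes}")


@dataclass
class SectionStack:
    """Ordered serial-section measurements for one cell.

    ``thickness`` is the section thickness in micrometres.  An optional
    ``supplied_length`` carries an externally measured cell length (used by
    :func:`cell_length` in ``supplied`` mode, e.g. when lengths were measured
    independently of the section count).
    """

    cell_id: str
    thickness: float
    sections: list[SectionMeasurement]
    supplied_length: float | None = None

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if len(self.sections) < 1:
            raise ValueError(f"stack {self.cell_id!r} has no sections")
        idx = [s.section_index for s in self.sections]
        for prev, cur in zip(idx, idx[1:]):
            if cur <= prev:
                raise ValueError(
                    f"stack {self.cell_id!r}: section indices not strictly "
                    f"increasing ({prev} then {cur})"
                )

    @property
    def n_sections(self) -> int:
        return len(self.sections)


@dataclass
class CellProfile:
    """Full structome profile of one cell (lengths um, areas um^2, volumes fl).

    ``ribosome_density`` is the count per 0.1 fl of cytoplasm.  For analytic
    (generator ground-truth) profiles ``ribosomes_total`` may be a non-integer
    expected count and ``n_sections`` is 0.
    """

    cell_id: str
    n_sections: int
    length: float
    diam_om: float
    diam_pm: float
    aspect_ratio: float
    surf_om: float
    surf_pm: float
    vol_whole: float
    vol_om: float
    vol_periplasm: float
    vol_pm: float
    vol_cytoplasm: float
    ribosomes_total: float
    ribosome_density: float

    #: Metric field names in the report-table order of the per-cell tables.
    METRICS = (
        "length", "diam_om", "diam_pm", "aspect_ratio",
        "surf_om", "surf_pm",
        "vol_whole", "vol_om", "vol_periplasm", "vol_pm", "vol_cytoplasm",
        "ribosomes_total", "ribosome_density",
    )


# ---------------------------------------------------------------------------
# one-dimensional estimators


def cell_length(stack: SectionStack,
                mode: Literal["section_count", "supplied"] = "section_count") -> float:
    """Cell length in micrometres.

    ``section_count`` multiplies the number of sections by the section
    thickness; ``supplied`` passes through an externally measured length
    attached to the stack.
    """
    if mode == "section_count":
        return stack.n_sections * stack.thickness
    if mode == "supplied":
        if stack.supplied_length is None:
            raise ValueError(f"stack {stack.cell_id!r} carries no supplied length")
        return stack.supplied_length
    raise ValueError(f"unknown length mode {mode!r}")


def cell_diameter(stack: SectionStack, boundary: Boundary = "OM",
                  estimator: Literal["median_central", "mean_all", "max"] = "median_central",
                  ) -> float:
    """Cell (OM) or cytoplasm (PM) diameter in micrometres.

    The default ``median_central`` takes the median of the minor-axis values
    over the central 50% of the sections with a positive axis, excluding the
    tapering polar sections; ``mean_all`` averages all positive sections and
    ``max`` returns the largest minor axis.
    """
    attr = "minor_om" if boundary == "OM" else "minor_pm"
    values = [getattr(s, attr) for s in stack.sections if getattr(s, attr) > 0]
    if not values:
        raise ValueError(f"stack {stack.cell_id!r}: no positive {attr} values")
    if estimator == "median_central":
        n = len(values)
        lo, hi = n // 4, n - n // 4
        return statistics.median(values[lo:hi])
    if estimator == "mean_all":
        return sum(values) / len(values)
    if estimator == "max":
        return max(values)
    raise ValueError(f"unknown diameter estimator {estimator!r}")


def aspect_ratio(length: float, diam_om: float) -> float:
    """Length / OM diameter (dimensionless)."""
    if not diam_om > 0:
        raise ValueError(f"diam_om must be > 0, got {diam_om}")
    return length / diam_om


# ---------------------------------------------------------------------------
# two- and three-dimensional estimators


def surface_area(stack: SectionStack, boundary: Boundary = "OM") -> float:
    """Membrane surface area by the trapezoid rule, in square micrometres.

    Consecutive section perimeters form the parallel sides of a trapezoid
    whose height is the section thickness:
    ``S = sum_i (p_i + p_{i-1}) / 2 * t``.  No end-cap correction is applied;
    the hemispherical poles are therefore systematically under-measured (the
    deficit for a spherocylinder of radius r and length L is about
    ``0.43 * r / L`` of the total, see the methods note).
    """
    if stack.n_sections < 2:
        raise ValueError("surface area needs at least 2 sections")
    p = [s.p_om if boundary == "OM" else s.p_pm for s in stack.sections]
    return sum((a + b) / 2.0 for a, b in zip(p, p[1:])) * stack.thickness


def compartment_volume(stack: SectionStack, boundary: Boundary = "OM") -> float:
    """Cavalieri volume in femtolitres (fl = um^3).

    Sums cross-sectional areas times the section thickness.  OM-lined areas
    give the whole-cell volume, PM-lined areas the cytoplasmic volume.
    Trailing or leading zero-area sections contribute nothing.
    """
    a = [s.a_om if boundary == "OM" else s.a_pm for s in stack.sections]
    return sum(a) * stack.thickness


def shell_volume(stack: SectionStack, membrane: Boundary = "OM",
                 default_thickness_nm: float | None = None) -> float:
    """Membrane shell volume in fl: perimeter x membrane thickness x height.

    Per-section membrane thicknesses (nm) are used when present; otherwise
    ``default_thickness_nm`` applies to every section.
    """
    total = 0.0
    for s in stack.sections:
        tau_nm = (s.om_thickness_nm if membrane == "OM" else s.pm_thickness_nm)
        if tau_nm is None:
            tau_nm = default_thickness_nm
        if tau_nm is None:
            raise ValueError(
                f"stack {stack.cell_id!r}: no {membrane} thickness for section "
                f"{s.section_index} and no default given"
            )
        p = s.p_om if membrane == "OM" else s.p_pm
        total += p * (tau_nm * 1e-3) * stack.thickness
    return total


def periplasm_volume(vol_whole: float, vol_cytoplasm: float,
                     vol_om: float = 0.0, vol_pm: float = 0.0,
                     mode: Literal["table_consistent", "text_literal"] = "table_consistent",
                     ) -> float:
    """Periplasm volume by subtraction, in fl.

    ``table_consistent`` (default) removes the OM and PM shells as well:
    ``whole - cytoplasm - OM - PM``; ``text_literal`` is the plain
    ``whole - cytoplasm``.  Negative results (possible with measurement
    noise) are clamped to zero with a warning.
    """
    if min(vol_whole, vol_cytoplasm, vol_om, vol_pm) < 0:
        raise ValueError("volumes must be >= 0")
    if mode == "table_consistent":
        v = vol_whole - vol_cytoplasm - vol_om - vol_pm
    elif mode == "text_literal":
        v = vol_whole - vol_cytoplasm
    else:
        raise ValueError(f"unknown periplasm mode {mode!r}")
    if v < 0:
        logger.warning("periplasm volume %.4g fl clamped to 0", v)
        return 0.0
    return v


# ---------------------------------------------------------------------------
# ribosomes


def ribosome_total(stack: SectionStack) -> int:
    """Total cytoplasmic ribosome count (sum of per-section counts)."""
    return sum(s.ribosomes for s in stack.sections)


def ribosome_density(total: float, vol_cytoplasm: float,
                     round_to: Literal["none", "nearest_10"] = "none") -> float:
    """Ribosomes per 0.1 fl of cytoplasm.

    ``nearest_10`` applies the reporting convention in which densities are
    quoted as multiples of ten.
    """
    if not vol_cytoplasm > 0:
        raise ValueError(f"vol_cytoplasm must be > 0, got {vol_cytoplasm}")
    d = total / vol_cytoplasm * 0.1
    if round_to == "nearest_10":
        return round_nearest_10(d)
    if round_to != "none":
        raise ValueError(f"unknown rounding {round_to!r}")
    return d


# ---------------------------------------------------------------------------
# rounding helpers (report-time conventions)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the report tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_nearest_10(x: float) -> float:
    """Round to the nearest multiple of 10, halves away from zero."""
    return round_half_away(x / 10.0) * 10.0


def round_profile(profile: CellProfile) -> CellProfile:
    """Apply report-table rounding: 2 dp for lengths/areas/volumes and the
    aspect ratio, nearest 10 for ribosome totals and densities."""
    two_dp = {
        name: round_half_away(getattr(profile, name), 2)
        for name in ("length", "diam_om", "diam_pm", "aspect_ratio",
                     "surf_om", "surf_pm", "vol_whole", "vol_om",
                     "vol_periplasm", "vol_pm", "vol_cytoplasm")
    }
    return replace(
        profile,
        ribosomes_total=round_nearest_10(profile.ribosomes_total),
        ribosome_density=round_nearest_10(profile.ribosome_density),
        **two_dp,
    )


# ---------------------------------------------------------------------------
# full profile


def quantify_cell(stack: SectionStack,
                  length_mode: Literal["section_count", "supplied"] = "section_count",
                  diameter_estimator: Literal["median_central", "mean_all", "max"] = "median_central",
                  periplasm_mode: Literal["table_consistent", "text_literal"] = "table_consistent",
                  om_thickness_nm: float | None = None,
                  pm_thickness_nm: float | None = None,
                  ) -> CellProfile:
    """Compute the complete structome profile of one cell.

    All quantities are computed at full precision; apply
    :func:`round_profile` (or the table writers) for report rounding.
    Membrane shell volumes require per-section thicknesses in the stack or
    the ``om_thickness_nm`` / ``pm_thickness_nm`` defaults; when neither is
    available the shells are reported as 0 with a warning.
    """
    length = cell_length(stack, mode=length_mode)
    diam_om = cell_diameter(stack, "OM", diameter_estimator)
    diam_pm = cell_diameter(stack, "PM", diameter_estimator)
    surf_om = surface_area(stack, "OM")
    surf_pm = surface_area(stack, "PM")
    vol_whole = compartment_volume(stack, "OM")
    vol_cyt = compartment_volume(stack, "PM")

    def shell(membrane: Boundary, default_nm: float | None) -> float:
        try:
            return shell_volume(stack, membrane, default_thickness_nm=default_nm)
        except ValueError:
            logger.warning(
                "stack %r: no %s membrane thickness available; shell volume set to 0",
                stack.cell_id, membrane,
            )
            return 0.0

    vol_om = shell("OM", om_thickness_nm)
    vol_pm = shell("PM", pm_thickness_nm)
    vol_peri = periplasm_volume(vol_whole, vol_cyt, vol_om, vol_pm, mode=periplasm_mode)

    total = ribosome_total(stack)
    density = ribosome_density(total, vol_cyt) if vol_cyt > 0 else 0.0

    return CellProfile(
        cell_id=stack.cell_id,
        n_sections=stack.n_sections,
        length=length,
        diam_om=diam_om,
        diam_pm=diam_pm,
        aspect_ratio=aspect_ratio(length, diam_om),
        surf_om=surf_om,
        surf_pm=surf_pm,
        vol_whole=vol_whole,
        vol_om=vol_om,
        vol_periplasm=vol_peri,
        vol_pm=vol_pm,
        vol_cytoplasm=vol_cyt,
        ribosomes_total=total,
        ribosome_density=density,
    )
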