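"""Stereology estimators: lengths, diameters, trapezoid surfaces, volumes."""

import logging
import math

import pytest
from hypothesis import given, strategies as st

from structome import (
    SectionMeasurement,
    SectionStack,
    aspect_ratio,
    cell_diameter,
    cell_length,
    compartment_volume,
    periplasm_volume,
    quantify_cell,
    ribosome_density,
    ribosome_total,
    shell_volume,
    surface_area,
)
from structome.stereology import round_half_away, round_nearest_10, round_profile


def _stack(perims=None, areas=None, thickness=0.04, minors=None, ribos=None,
           om_nm=None, pm_nm=None, supplied_length=None):
    n = max(len(x) for x in (perims, areas, minors, ribos) if x is not None)
    perims = perims or [0.0] * n
    areas = areas or [0.0] * n
    minors = minors or [0.0] * n
    ribos = ribos or [0] * n
    sections = [
        SectionMeasurement(
            section_index=i + 1,
            p_om=perims[i], p_pm=perims[i],
            a_om=areas[i], a_pm=areas[i],
            minor_om=minors[i], major_om=minors[i],
            minor_pm=minors[i], major_pm=minors[i],
            ribosomes=ribos[i],
            om_thickness_nm=om_nm, pm_thickness_nm=pm_nm,
        )
        for i in range(n)
    ]
    return SectionStack(cell_id="test", thickness=thickness, sections=sections,
                        supplied_length=supplied_length)


class TestCellLength:
    def test_section_count_mode(self):
        assert cell_length(_stack(areas=[0.1] * 89, thickness=0.04)) == \
            pytest.approx(3.56)

    def test_single_section(self):
        assert cell_length(_stack(areas=[0.1], thickness=0.055)) == \
            pytest.approx(0.055)

    def test_supplied_mode(self):
        stack = _stack(areas=[0.1] * 38, thickness=0.055, supplied_length=3.90)
        # 38 sections x 55 nm = 2.09 um: the two modes measure different things
        assert cell_length(stack, "section_count") == pytest.approx(2.09)
        assert cell_length(stack, "supplied") == 3.90

    def test_supplied_mode_requires_length(self):
        with pytest.raises(ValueError):
            cell_length(_stack(areas=[0.1] * 3), "supplied")


class TestCellDiameter:
    def test_constant_axis_all_estimators_agree(self):
        stack = _stack(minors=[0.58] * 20)
        for est in ("median_central", "mean_all", "max"):
            assert cell_diameter(stack, "OM", est) == pytest.approx(0.58)

    def test_central_median_excludes_tapering_poles(self):
        minors = [0.1, 0.3] + [0.58] * 16 + [0.3, 0.1]
        assert cell_diameter(_stack(minors=minors)) == pytest.approx(0.58)
        assert cell_diameter(_stack(minors=minors), estimator="mean_all") < 0.58

    def test_all_zero_axes_rejected(self):
        with pytest.raises(ValueError):
            cell_diameter(_stack(minors=[0.0] * 5))


class TestAspectRatio:
    # printed per-cell (length, OM diameter, aspect) rows round-trip within
    # the rounding of the 2-dp inputs
    @pytest.mark.parametrize("length,diam,printed,tol", [
        (3.90, 0.59, 6.63, 0.05),
        (7.41, 0.52, 14.35, 0.15),
    ])
    def test_printed_rows(self, length, diam, printed, tol):
        assert aspect_ratio(length, diam) == pytest.approx(printed, abs=tol)

    def test_unit_ratio(self):
        assert aspect_ratio(2.5, 2.5) == 1.0

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            aspect_ratio(1.0, 0.0)


class TestSurfaceArea:
    def test_constant_perimeter(self):
        assert surface_area(_stack(perims=[2.0] * 5, thickness=0.04)) == \
            pytest.approx(4 * 2.0 * 0.04)

    def test_hand_computed_trapezoid_sum(self):
        stack = _stack(perims=[0, 1, 2, 1, 0], thickness=0.1)
        assert surface_area(stack) == pytest.approx(0.40)

    def test_requires_two_sections(self):
        with pytest.raises(ValueError):
            surface_area(_stack(perims=[1.0]))


class TestCompartmentVolume:
    def test_prism(self):
        assert compartment_volume(_stack(areas=[0.25] * 10, thickness=0.04)) == \
            pytest.approx(0.10)

    def test_zero_padding_invariance(self):
        v = compartment_volume(_stack(areas=[0.25] * 10))
        v_pad = compartment_volume(_stack(areas=[0.0] * 3 + [0.25] * 10 + [0.0] * 4))
        assert v_pad == pytest.approx(v)


class TestShellVolume:
    def test_direct_product(self):
        stack = _stack(perims=[1.8] * 20, thickness=0.04, om_nm=5.0)
        assert shell_volume(stack, "OM") == pytest.approx(1.8 * 0.005 * 0.04 * 20)

    def test_zero_thickness(self):
        stack = _stack(perims=[1.8] * 20, om_nm=0.0)
        assert shell_volume(stack, "OM") == 0.0

    def test_thin_shell_matches_surface_times_thickness(self):
        stack = _stack(perims=[1.8] * 20, thickness=0.04, om_nm=5.0)
        approx = surface_area(stack, "OM") * 0.005
        # constant-perimeter stacks: only the half-interval ends differ
        assert shell_volume(stack, "OM") == pytest.approx(approx, rel=0.06)

    def test_missing_thickness_rejected(self):
        with pytest.raises(ValueError):
            shell_volume(_stack(perims=[1.8] * 5), "OM")

    def test_stack_level_default(self):
        stack = _stack(perims=[1.8] * 5)
        assert shell_volume(stack, "PM", default_thickness_nm=6.0) == \
            pytest.approx(1.8 * 0.006 * 0.04 * 5)


class TestPeriplasmVolume:
    # printed volume rows: whole, cytoplasm, OM, PM -> periplasm
    @pytest.mark.parametrize("whole,cyt,om,pm,printed", [
        (1.06, 0.82, 0.01, 0.03, 0.19),
        (1.07, 0.96, 0.01, 0.03, 0.07),
    ])
    def test_table_consistent_reproduces_printed(self, whole, cyt, om, pm, printed):
        v = periplasm_volume(whole, cyt, om, pm)
        assert v == pytest.approx(printed, abs=0.015)

    def test_text_literal_mode(self):
        assert periplasm_volume(1.06, 0.82, 0.01, 0.03, mode="text_literal") == \
            pytest.approx(0.24)

    def test_degenerate_zero(self):
        assert periplasm_volume(0.5, 0.5) == 0.0

    def test_negative_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            v = periplasm_volume(0.5, 0.6, 0.01, 0.01)
        assert v == 0.0
        assert "clamped" in caplog.text


class TestRibosomes:
    def test_total_is_sum(self):
        assert ribosome_total(_stack(ribos=[245] * 38)) == 245 * 38
        assert ribosome_total(_stack(ribos=[0] * 5)) == 0

    def test_per_section_mean_matches_printed_row(self):
        # printed: total 9290 over 38 sections, "number per section" 245
        assert 9290 / 38 == pytest.approx(245, abs=1)

    @pytest.mark.parametrize("total,vol,expect", [
        (8210, 0.58, 1420),
        (12930, 1.30, 990),
        (0, 0.5, 0),
    ])
    def test_density_nearest_10(self, total, vol, expect):
        assert ribosome_density(total, vol, round_to="nearest_10") == expect

    def test_density_full_precision(self):
        assert ribosome_density(8210, 0.58) == pytest.approx(1415.517, abs=1e-3)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            ribosome_density(100, 0.0)


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(2.675, 2) == 2.68

    def test_nearest_10(self):
        assert round_nearest_10(1415.5) == 1420
        assert round_nearest_10(994.6) == 990
        assert round_nearest_10(245.0) == 250


class TestQuantifyCell:
    def _full_stack(self):
        # PM strictly inside OM so the periplasm remainder stays positive
        stack = _stack(perims=[1.8] * 20, areas=[0.25] * 20,
                       minors=[0.57] * 20, ribos=[100] * 20,
                       om_nm=2.0, pm_nm=6.0)
        from dataclasses import replace
        stack.sections = [
            replace(s, p_pm=s.p_om * 0.95, a_pm=s.a_om * 0.9,
                    minor_pm=s.minor_om * 0.95, major_pm=s.major_om * 0.95)
            for s in stack.sections
        ]
        return stack

    def test_profile_fields_consistent(self):
        p = quantify_cell(self._full_stack())
        assert p.n_sections == 20
        assert p.length == pytest.approx(0.8)
        assert p.aspect_ratio == pytest.approx(p.length / p.diam_om)
        assert p.ribosomes_total == 2000
        assert p.ribosome_density == pytest.approx(2000 / p.vol_cytoplasm * 0.1)

    def test_volume_additivity_identity(self):
        p = quantify_cell(self._full_stack())
        assert p.vol_om + p.vol_periplasm + p.vol_pm + p.vol_cytoplasm == \
            pytest.approx(p.vol_whole, rel=1e-12)

    def test_single_section_raises_for_surface(self):
        stack = _stack(perims=[1.8], areas=[0.25], minors=[0.57])
        with pytest.raises(ValueError):
            quantify_cell(stack)

    def test_missing_membrane_thickness_warns_and_zeroes(self, caplog):
        stack = _stack(perims=[1.8] * 5, areas=[0.25] * 5, minors=[0.57] * 5)
        with caplog.at_level(logging.WARNING):
            p = quantify_cell(stack)
        assert p.vol_om == 0.0 and p.vol_pm == 0.0
        assert "shell volume" in caplog.text

    def test_round_profile_conventions(self):
        p = round_profile(quantify_cell(self._full_stack()))
        assert p.ribosomes_total % 10 == 0
        assert p.vol_whole == round_half_away(0.25 * 20 * 0.04, 2)


@given(
    scale=st.floats(min_value=0.1, max_value=10),
    perims=st.lists(st.floats(min_value=0, max_value=5), min_size=3, max_size=30),
)
def test_scale_equivariance(scale, perims):
    """Scaling all lengths by c scales surfaces by c^2 and volumes by c^3."""
    areas = [p ** 2 / (4 * math.pi) for p in perims]  # circle-consistent
    base = _stack(perims=perims, areas=areas, thickness=0.04)
    scaled = _stack(perims=[p * scale for p in perims],
                    areas=[a * scale ** 2 for a in areas],
                    thickness=0.04 * scale)
    assert surface_area(scaled) == pytest.approx(
        surface_area(base) * scale ** 2, rel=1e-9, abs=1e-12)
    assert compartment_volume(scaled) == pytest.approx(
        compartment_volume(base) * scale ** 3, rel=1e-9, abs=1e-12)
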