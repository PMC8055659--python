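"""Co-expression rules, panel definitions, densities, and percentages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mifspat as m
from mifspat.phenotyping import TOTAL_PHENOTYPE, PhenotypeRule

from conftest import make_frame


class TestRuleParsing:
    @pytest.mark.parametrize(
        "name,pos,neg",
        [
            ("CD3+CD8+", {"CD3", "CD8"}, set()),
            ("CD3+FOXP3+CD8-", {"CD3", "FOXP3"}, {"CD8"}),
            ("CK+PD-L1+", {"CK", "PD-L1"}, set()),
            ("CD3+B7-H4+", {"CD3", "B7-H4"}, set()),
            ("CD11b+Arg-1+CD14+CD33+", {"CD11b", "Arg-1", "CD14", "CD33"}, set()),
            ("CD3+OX-40+", {"CD3", "OX-40"}, set()),
        ],
    )
    def test_field_notation_with_hyphenated_markers(self, name, pos, neg):
        rule = PhenotypeRule.from_name(name)
        assert rule.positive == frozenset(pos)
        assert rule.negative == frozenset(neg)

    def test_unparseable_notation_errors(self):
        with pytest.raises(m.ParameterError, match="cannot parse"):
            PhenotypeRule.from_name("NOTAMARKER+")

    def test_empty_positive_set_rejected(self):
        with pytest.raises(m.ParameterError, match="empty positive"):
            PhenotypeRule(name="CD8-", positive=frozenset(), negative=frozenset({"CD8"}))

    def test_conflicting_sign_rejected(self):
        with pytest.raises(m.ParameterError, match="both positive and negative"):
            PhenotypeRule(name="x", positive=frozenset({"CD3"}), negative=frozenset({"CD3"}))


class TestDefaultPanels:
    def test_five_panels_with_expected_markers(self):
        panels = m.default_panels()
        assert sorted(panels) == ["1", "2", "3", "4", "5"]
        assert panels["1"].markers == ["CK", "CD3", "CD8", "PD-1", "PD-L1", "CD68"]
        assert panels["3"].markers == ["CK", "CD3", "PD-L1", "B7-H3", "B7-H4", "IDO-1", "CD68"]

    def test_rule_counts_per_panel(self):
        panels = m.default_panels()
        assert {pid: len(p.rules) for pid, p in panels.items()} == {
            "1": 8, "2": 7, "3": 15, "4": 7, "5": 7,
        }

    def test_rule_referencing_undeclared_marker_is_spec_error(self):
        with pytest.raises(m.ValidationError, match="undeclared"):
            m.PanelSpec(
                panel_id="x", markers=["CD3"],
                rules=[PhenotypeRule.from_name("CD3+CD8+")],
            )


class TestAssignPhenotypes:
    def test_cytotoxic_t_cell_memberships_are_non_exclusive(self, panel1):
        f = make_frame(
            [("c1", 1.0, 1.0, {"CD3": True, "CD8": True})], panel1.markers
        )
        member = m.assign_phenotypes(f, panel1)
        assert "c1" in member["CD3+"]
        assert "c1" in member["CD3+CD8+"]
        assert "c1" not in member["CD3+PD-1+"]
        assert "c1" not in member["CK+"]

    def test_all_negative_cell_belongs_to_no_rule(self, panel1):
        f = make_frame([("c1", 1.0, 1.0, {})], panel1.markers)
        member = m.assign_phenotypes(f, panel1)
        assert all(not ids for ids in member.values())

    def test_ten_cell_frame_matches_hand_enumeration(self, panel2):
        # hand enumeration over panel 2 including the CD8- requirement of Tregs
        cells = [
            ("c0", 0, 0, {"CD3": 1, "FOXP3": 1}),            # Treg
            ("c1", 1, 0, {"CD3": 1, "FOXP3": 1, "CD8": 1}),  # not Treg (CD8+)
            ("c2", 2, 0, {"CD3": 1, "CD8": 1}),
            ("c3", 3, 0, {"CD3": 1, "CD8": 1, "GBZ": 1}),
            ("c4", 4, 0, {"CD3": 1, "CD45RO": 1}),
            ("c5", 5, 0, {"CD3": 1, "CD8": 1, "CD45RO": 1}),
            ("c6", 6, 0, {"CK": 1}),
            ("c7", 7, 0, {"CK": 1}),
            ("c8", 8, 0, {"FOXP3": 1}),                      # no CD3 -> nothing
            ("c9", 9, 0, {}),
        ]
        f = make_frame(cells, panel2.markers)
        member = m.assign_phenotypes(f, panel2)
        counts = {name: len(ids) for name, ids in member.items()}
        assert counts == {
            "CK+": 2,
            "CD3+": 6,
            "CD3+CD8+": 4,
            "CD3+CD8+GBZ+": 1,
            "CD3+CD45RO+": 2,
            "CD3+CD8+CD45RO+": 1,
            "CD3+FOXP3+CD8-": 1,
        }

    def test_subset_monotonicity_of_rule_counts(self, panel1, small_cohort):
        frames, _ = small_cohort
        for f in frames[:4]:
            member = m.assign_phenotypes(f, panel1)
            assert len(member["CD3+CD8+PD-1+"]) <= len(member["CD3+CD8+"]) <= len(member["CD3+"])
            assert len(member["CK+PD-L1+"]) <= len(member["CK+"])


class TestDensities:
    def test_density_hand_arithmetic_on_roi_field(self, panel1):
        # 650 CK+ cells on the 931x698 um field: 650 / 0.649838 mm2
        cells = [(f"c{i}", 1.0 + 0.9 * i, 2.0, {"CK": True}) for i in range(650)]
        f = make_frame(cells, panel1.markers)
        dens = m.compute_densities(f, panel1)
        ck = dens.loc[dens["phenotype"] == "CK+", "density_cells_mm2"].item()
        assert ck == pytest.approx(650 / 0.649838, rel=1e-9)
        assert ck == pytest.approx(1000.25, abs=0.005)

    def test_zero_matching_cells_zero_density(self, panel1):
        f = make_frame([("c1", 1.0, 1.0, {"CK": True})], panel1.markers)
        dens = m.compute_densities(f, panel1)
        assert dens.loc[dens["phenotype"] == "CD3+", "density_cells_mm2"].item() == 0.0

    def test_unit_area_roi_density_equals_count(self, panel1):
        f = make_frame(
            [(f"c{i}", 10.0 * i, 2.0, {"CK": True}) for i in range(7)],
            panel1.markers, width=1000.0, height=1000.0,
        )
        dens = m.compute_densities(f, panel1)
        assert dens.loc[dens["phenotype"] == "CK+", "density_cells_mm2"].item() == 7.0

    def test_zero_area_errors(self, panel1):
        f = make_frame([], panel1.markers)
        f.width = 0.0
        with pytest.raises(m.MifspatError):
            m.compute_densities(f, panel1)

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_density_scales_inversely_with_area(self, scale):
        panel = m.PanelSpec(panel_id="t", markers=["CK"],
                            rules=[PhenotypeRule.from_name("CK+")])
        cells = [(f"c{i}", 0.5, 0.5, {"CK": True}) for i in range(5)]
        base = make_frame(cells, ["CK"], width=100.0, height=100.0)
        scaled = make_frame(cells, ["CK"], width=100.0 * scale, height=100.0)
        d0 = m.compute_densities(base, panel)
        d1 = m.compute_densities(scaled, panel)
        ratio = (d0.loc[d0.phenotype == "CK+", "density_cells_mm2"].item()
                 / d1.loc[d1.phenotype == "CK+", "density_cells_mm2"].item())
        assert ratio == pytest.approx(scale, rel=1e-9)


class TestPercentOfTotal:
    def test_simple_fraction(self, panel1):
        cells = [(f"t{i}", 1.0 * i, 1.0, {"CD3": True}) for i in range(50)]
        cells += [(f"o{i}", 1.0 * i, 2.0, {}) for i in range(150)]
        f = make_frame(cells, panel1.markers)
        dens = m.percent_of_total(m.compute_densities(f, panel1))
        assert dens.loc[dens.phenotype == "CD3+", "percent_dapi"].item() == 25.0

    def test_phenotype_equal_to_total_is_100(self, panel1):
        cells = [(f"c{i}", 1.0 * i, 1.0, {"CK": True}) for i in range(10)]
        f = make_frame(cells, panel1.markers)
        dens = m.percent_of_total(m.compute_densities(f, panel1))
        assert dens.loc[dens.phenotype == "CK+", "percent_dapi"].item() == 100.0

    def test_percent_invariant_to_area(self, panel1):
        cells = [(f"c{i}", 1.0 * i, 1.0, {"CK": i % 2 == 0}) for i in range(10)]
        small = make_frame(cells, panel1.markers, width=100.0, height=100.0)
        big = make_frame(cells, panel1.markers, width=900.0, height=600.0)
        ps = m.percent_of_total(m.compute_densities(small, panel1))
        pb = m.percent_of_total(m.compute_densities(big, panel1))
        assert ps["percent_dapi"].tolist() == pb["percent_dapi"].tolist()

    def test_zero_total_group_keeps_nan_percent(self, panel1, caplog):
        f = make_frame([], panel1.markers)
        dens = m.compute_densities(f, panel1)
        with caplog.at_level("WARNING"):
            out = m.percent_of_total(dens)
        assert out["percent_dapi"].isna().all()

    def test_exclusive_base_classes_sum_to_100(self, panel1, small_cohort):
        frames, _ = small_cohort
        f = frames[0]
        dens = m.percent_of_total(m.compute_densities(f, panel1))
        pct = dens.set_index("phenotype")["percent_dapi"]
        n_other = (~f.cells[["CK", "CD3", "CD68"]].any(axis=1)).sum()
        other_pct = 100.0 * n_other / f.n_cells
        total = pct["CK+"] + pct["CD3+"] + pct["CD68+"] + other_pct
        assert total == pytest.approx(100.0, abs=1e-9)
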