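"""Mixing-ratio quantification, domain classification and structure mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ihp import xlms
from ihp.xlms import DEFAULT_DOMAIN_MAP, DomainMap

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestNitrogenCount:
    @pytest.mark.parametrize("pep,n", [("GK", 3), ("R", 4), ("AAA", 3)])
    def test_known_counts(self, pep, n):
        assert xlms.nitrogen_count(pep) == n

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="Z"):
            xlms.nitrogen_count("GKZ")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            xlms.nitrogen_count("")

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.text(alphabet=AA, min_size=1, max_size=20),
        b=st.text(alphabet=AA, min_size=1, max_size=20),
    )
    def test_additive_over_concatenation(self, a, b):
        assert xlms.nitrogen_count(a + b) == xlms.nitrogen_count(a) + xlms.nitrogen_count(b)


class TestChannelMasses:
    def test_shift_additivity(self):
        m = xlms.channel_masses("PEPTIDE", "KRR")
        assert m.m_lh + m.m_hl == pytest.approx(m.m_ll + m.m_hh, abs=1e-9)

    def test_heavy_heavy_shift_from_nitrogen_counts(self):
        m = xlms.channel_masses("GK", "AK")
        assert m.m_hh - m.m_ll == pytest.approx(0.997035 * 6, abs=1e-9)

    def test_linker_contribution(self):
        m = xlms.channel_masses("GK", "AK")
        expected = xlms.peptide_mono_mass("GK") + xlms.peptide_mono_mass("AK") + 138.068
        assert m.m_ll == pytest.approx(expected, abs=1e-9)

    def test_strict_mass_ordering(self):
        m = xlms.channel_masses("GK", "AK")
        assert m.m_ll < m.m_lh < m.m_hh and m.m_ll < m.m_hl < m.m_hh


class TestMixingRatio:
    def test_no_heterotypic_signal_gives_zero(self):
        for variant in ("homotypic_sum", "as_printed"):
            assert xlms.mixing_ratio(100, 0, 0, 150, denominator=variant) == 0.0

    def test_homotypic_sum_arithmetic(self):
        assert xlms.mixing_ratio(100, 20, 30, 150) == pytest.approx(50 / 250)

    def test_as_printed_arithmetic(self):
        assert xlms.mixing_ratio(100, 20, 30, 150, denominator="as_printed") == pytest.approx(
            50 / 120
        )

    def test_zero_denominator_flagged_undefined(self):
        rec = {"I_LL": 0.0, "I_LH": 10.0, "I_HL": 5.0, "I_HH": 0.0}
        q = xlms.compute_R(rec)
        assert not q.defined and np.isnan(q.R)

    @settings(derandomize=True, max_examples=50)
    @given(
        i=st.tuples(*[st.floats(0.1, 1e6)] * 4),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_invariance_and_label_swap(self, i, scale):
        ll, lh, hl, hh = i
        r = xlms.mixing_ratio(ll, lh, hl, hh)
        assert xlms.mixing_ratio(scale * ll, scale * lh, scale * hl, scale * hh) == pytest.approx(r)
        # swapping light/heavy labels swaps LL<->HH and LH<->HL
        assert xlms.mixing_ratio(hh, hl, lh, ll) == pytest.approx(r)


class TestDomainMap:
    def test_interior_kinase_position(self):
        assert xlms.classify_domain(100) == "kinase"

    def test_hub_boundary_positions(self):
        assert xlms.classify_domain(344) == "hub"
        assert xlms.classify_domain(347) == "hub"

    def test_out_of_span_rejected(self):
        with pytest.raises(ValueError):
            xlms.classify_domain(500)

    def test_gapped_map_rejected(self):
        with pytest.raises(ValueError):
            DomainMap({"a": (1, 10), "b": (12, 20)})

    def test_domain_pair_is_unordered(self):
        assert xlms.domain_pair(100, 400) == xlms.domain_pair(400, 100) == ("kinase", "hub")


class TestHeatmap:
    def test_empty_input_all_zero(self):
        empty = pd.DataFrame(
            columns=["pos_a", "pos_b", "replicate", "I_LL", "I_LH", "I_HL", "I_HH"]
        )
        m = xlms.build_heatmap(empty)
        assert (m.to_numpy() == 0).all()

    def test_ihp_heterotypic_only_kinase_kinase(self, ihp_xl_table):
        m = xlms.build_heatmap(ihp_xl_table, mode="heterotypic")
        assert m.loc["kinase", "kinase"] > 0
        off = m.to_numpy().sum() - m.loc["kinase", "kinase"]
        assert off == 0

    def test_intersection_excludes_single_replicate_records(self, ihp_xl_table):
        extra = ihp_xl_table.iloc[[0]].copy()
        extra["pos_a"], extra["pos_b"] = 9999, 9998  # only in replicate 1
        # place within span instead
        extra["pos_a"], extra["pos_b"] = 21, 467
        extra["replicate"] = 1
        table = pd.concat([ihp_xl_table, extra], ignore_index=True)
        with_int = xlms.build_heatmap(table, mode="heterotypic", require_both_replicates=True)
        without = xlms.build_heatmap(table, mode="heterotypic", require_both_replicates=False)
        assert with_int.to_numpy().sum() <= without.to_numpy().sum()

    def test_totals_conserved(self, ihp_xl_table):
        het = xlms.build_heatmap(ihp_xl_table, mode="heterotypic")
        hom = xlms.build_heatmap(ihp_xl_table, mode="homotypic")
        n_unique = len({(min(a, b), max(a, b))
                        for a, b in zip(ihp_xl_table.pos_a, ihp_xl_table.pos_b)})
        assert het.to_numpy().sum() + hom.to_numpy().sum() == n_unique

    def test_single_replicate_intersection_rejected(self, ihp_xl_table):
        one = ihp_xl_table[ihp_xl_table["replicate"] == 1]
        with pytest.raises(ValueError, match="replicate"):
            xlms.build_heatmap(one, require_both_replicates=True)


class TestSummaries:
    def test_single_record(self):
        df = pd.DataFrame(
            {"pos_a": [100], "pos_b": [150], "replicate": [1],
             "I_LL": [100.0], "I_LH": [10.0], "I_HL": [10.0], "I_HH": [100.0]}
        )
        q = xlms.quantify(df)
        out = xlms.summarize_ratios(q)
        assert len(out) == 1
        assert out.iloc[0]["mean_R"] == pytest.approx(0.1)
        assert out.iloc[0]["se_R"] == 0.0
        assert out.iloc[0]["n"] == 1

    def test_ihp_kinase_mean_near_target(self, ihp_xl_table):
        q = xlms.quantify(ihp_xl_table)
        out = xlms.summarize_ratios(q).set_index("domain_pair")
        row = out.loc["kinase-kinase"]
        assert abs(row["mean_R"] - 0.25) <= max(2 * row["se_R"], 0.02)

    def test_all_undefined_group_omitted(self):
        df = pd.DataFrame(
            {"pos_a": [400], "pos_b": [420], "replicate": [1],
             "I_LL": [0.0], "I_LH": [0.0], "I_HL": [0.0], "I_HH": [0.0]}
        )
        out = xlms.summarize_ratios(xlms.quantify(df))
        assert out.empty


class TestStructureMapping:
    @staticmethod
    def _records(pairs):
        return pd.DataFrame([{"pos_a": a, "pos_b": b} for a, b in pairs])

    def test_identical_coordinates_zero_distance(self):
        coords = {"A": {10: np.zeros(3), 20: np.zeros(3)}}
        out = xlms.map_to_structure(self._records([(10, 20)]), coords, pairing="intra_subunit")
        assert out.iloc[0]["distance"] == 0.0 and out.iloc[0]["satisfied"]

    def test_euclidean_distance(self):
        coords = {"A": {10: np.array([0.0, 0.0, 0.0]), 20: np.array([3.0, 4.0, 0.0])}}
        out = xlms.map_to_structure(self._records([(10, 20)]), coords, pairing="intra_subunit")
        assert out.iloc[0]["distance"] == pytest.approx(5.0)

    def test_all_pairs_beyond_threshold_unsatisfied(self):
        coords = {"A": {10: np.zeros(3)}, "B": {20: np.array([100.0, 0.0, 0.0])}}
        out = xlms.map_to_structure(
            self._records([(10, 20)]), coords, pairing="inter_subunit_min", max_dist=30.0
        )
        assert out["mapped"].all() and not out["satisfied"].any()

    def test_missing_residue_flagged_not_dropped(self):
        coords = {"A": {10: np.zeros(3)}}
        out = xlms.map_to_structure(self._records([(10, 99)]), coords, pairing="intra_subunit")
        assert len(out) == 1 and not out.iloc[0]["mapped"]

    def test_symmetry_and_rigid_motion_invariance(self, rng):
        coords = {
            "A": {10: rng.normal(size=3), 20: rng.normal(size=3)},
            "B": {10: rng.normal(size=3), 20: rng.normal(size=3)},
        }
        fwd = xlms.map_to_structure(self._records([(10, 20)]), coords)
        rev = xlms.map_to_structure(self._records([(20, 10)]), coords)
        assert fwd.iloc[0]["distance"] == pytest.approx(rev.iloc[0]["distance"], abs=1e-9)
        # rigid-body rotation + translation preserves distances
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        shift = np.array([5.0, -2.0, 3.0])
        moved = {ch: {r: rot @ xyz + shift for r, xyz in res.items()}
                 for ch, res in coords.items()}
        after = xlms.map_to_structure(self._records([(10, 20)]), moved)
        assert after.iloc[0]["distance"] == pytest.approx(fwd.iloc[0]["distance"], abs=1e-6)

    def test_pseudobond_file_round_trip(self, tmp_path):
        coords = {"A": {10: np.zeros(3)}, "B": {20: np.array([3.0, 4.0, 0.0])}}
        pb = tmp_path / "links.pb"
        xlms.map_to_structure(
            self._records([(10, 20)]), coords, pairing="inter_subunit_min",
            pseudobond_path=str(pb),
        )
        lines = [l for l in pb.read_text().splitlines() if not l.startswith(";")]
        assert lines == ["/A:10@CA /B:20@CA"]

    def test_pdb_loading(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A  10      0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A  10      1.000   2.000   2.000  1.00  0.00           C\n"
            "ATOM      3  CA  GLY A  11      4.000   6.000   2.000  1.00  0.00           C\n"
            "END\n"
        )
        coords = xlms.load_ca_coordinates(str(pdb))
        assert set(coords["A"]) == {10, 11}
        d = np.linalg.norm(coords["A"][10] - coords["A"][11])
        assert d == pytest.approx(5.0)
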