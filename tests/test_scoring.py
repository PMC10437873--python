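"""Substrate-group mapping, necromass fraction, and the survey score table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermenz import AbundanceMatrix
from thermenz.scoring import (
    fluid_sediment_summary,
    group_abundance,
    necromass_fraction,
    round_fraction,
    score_table,
    threshold_counts,
)
from thermenz.io import SiteMetadata


class TestSubstrateMap:
    def test_peptidoglycan_members(self, substrate_map):
        pep = substrate_map.families("peptidoglycan")
        assert {"GH23", "CBM50", "CE4", "M23", "S11"} <= pep

    def test_gh5_in_three_groups(self, substrate_map):
        for group in ("chitin", "xylan", "cellulose"):
            assert "GH5" in substrate_map.families(group)

    def test_supergroup_unions(self, substrate_map):
        cell = substrate_map.supergroup_families("cell", ("CAZY",))
        photo = substrate_map.supergroup_families("photosynthate", ("CAZY",))
        assert "GH23" in cell and "GH18" in cell
        assert "GH11" in photo and "GH116" in photo
        assert {"GH5", "GH7", "GH8"} <= cell & photo  # shared families

    def test_exclusive_dedup_drops_shared_families(self, substrate_map):
        cell = substrate_map.supergroup_families("cell", ("CAZY",), dedup="exclusive")
        photo = substrate_map.supergroup_families("photosynthate", ("CAZY",),
                                                  dedup="exclusive")
        assert not cell & photo

    def test_unknown_supergroup_is_error(self, substrate_map):
        with pytest.raises(KeyError, match="starch"):
            substrate_map.supergroup_families("starch")


class TestGroupAbundance:
    def test_hand_computed_dedup_example(self, toy_matrix, substrate_map):
        """GH23=2, GH5=1, GH11=3 in S1: cell = GH23+GH5 = 3; photosynthate =
        GH5 (once, though in both xylan and cellulose) + GH11 = 4."""
        cell = group_abundance(toy_matrix, substrate_map, "cell")
        photo = group_abundance(toy_matrix, substrate_map, "photosynthate")
        assert cell["S1"] == pytest.approx(3.0)
        assert photo["S1"] == pytest.approx(4.0)

    def test_all_zero_column(self, substrate_map):
        m = AbundanceMatrix("CAZY", pd.DataFrame({"S1": [0.0]}, index=["GH23"]))
        assert group_abundance(m, substrate_map, "cell")["S1"] == 0.0

    def test_matches_brute_force_over_pairs(self, substrate_map, rng):
        fams = ["GH23", "GH18", "GH5", "GH11", "GH43", "GH13", "GT2"]
        data = pd.DataFrame(rng.uniform(0, 10, (len(fams), 3)),
                            index=fams, columns=["A", "B", "C"])
        m = AbundanceMatrix("CAZY", data)
        cell_fams = substrate_map.supergroup_families("cell", ("CAZY",))
        brute = data.loc[[f for f in fams if f in cell_fams]].sum(axis=0)
        out = group_abundance(m, substrate_map, "cell")
        assert np.allclose(out.to_numpy(), brute.to_numpy())

    def test_supergroup_sum_bounded_by_column_total(self, toy_matrix, substrate_map):
        cell = group_abundance(toy_matrix, substrate_map, "cell")
        photo = group_abundance(toy_matrix, substrate_map, "photosynthate")
        col = toy_matrix.data.sum(axis=0)
        # each is a subset sum of the column
        assert (cell <= col + 1e-12).all() and (photo <= col + 1e-12).all()


class TestNecromassFraction:
    @pytest.mark.parametrize("cell,photo,expected", [
        (2303.35, 7311.38, 0.24),   # a low-fraction sediment spring
        (3362.49, 20.58, 0.99),     # an extreme fluid spring
        (61.39, 1.58, 0.97),        # a hot Iceland sediment
    ])
    def test_survey_rows_to_two_decimals(self, cell, photo, expected):
        assert round_fraction(necromass_fraction(cell, photo)) == expected

    def test_boundary_photo_zero(self):
        assert necromass_fraction(5.0, 0.0) == 1.0

    def test_both_zero_is_flagged_missing(self):
        assert math.isnan(necromass_fraction(0.0, 0.0))

    def test_negative_input_is_error(self):
        with pytest.raises(ValueError):
            necromass_fraction(-1.0, 2.0)

    @given(cell=st.floats(0, 1e6), photo=st.floats(0, 1e6),
           extra=st.floats(0, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_adding_cell_abundance_never_decreases_fraction(self, cell, photo, extra):
        if cell + photo == 0:
            return
        f0 = necromass_fraction(cell, photo)
        f1 = necromass_fraction(cell + extra, photo)
        assert f1 >= f0 - 1e-12
        assert 0.0 <= f1 <= 1.0


class TestScoreTable:
    def _meta(self, samples):
        return [SiteMetadata(s, s, province="P", temperature=30.0, pH=7.0)
                for s in samples]

    def test_sorted_ascending_with_totals(self, toy_matrix, substrate_map):
        df, totals = score_table(toy_matrix, substrate_map,
                                 self._meta(["S1", "S2", "S3", "S4"]))
        fr = df["necromass_fraction"].dropna()
        assert list(fr) == sorted(fr)
        assert totals["cell"] == pytest.approx(df["cell"].sum())
        assert totals["photosynthate"] == pytest.approx(df["photosynthate"].sum())

    def test_missing_metadata_error_names_sample(self, toy_matrix, substrate_map):
        with pytest.raises(KeyError, match="S4"):
            score_table(toy_matrix, substrate_map, self._meta(["S1", "S2", "S3"]))

    def test_empty_sample_set(self, substrate_map):
        m = AbundanceMatrix("CAZY", pd.DataFrame(index=["GH23"], columns=[], dtype=float))
        df, totals = score_table(m, substrate_map)
        assert df.empty and totals == {"cell": 0.0, "photosynthate": 0.0}

    def test_undefined_fraction_emitted_not_dropped(self, substrate_map):
        m = AbundanceMatrix("CAZY", pd.DataFrame({"S1": [0.0]}, index=["GH23"]))
        df, _ = score_table(m, substrate_map)
        assert len(df) == 1 and math.isnan(df["necromass_fraction"].iloc[0])


class TestFluidSedimentSummary:
    def test_two_sample_sums(self):
        df = pd.DataFrame({
            "sample_id": ["A1F", "A2S"], "cell": [1.0, 2.0],
            "photosynthate": [0.5, 3.0], "province": ["P", "P"],
            "sample_type": ["fluid", "sediment"],
        })
        grouped, cmp = fluid_sediment_summary(df)
        f = grouped.set_index("sample_type")
        assert f.at["fluid", "cell"] == 1.0 and f.at["sediment", "cell"] == 2.0
        assert cmp["photosynthate_richer_in_sediments"]


class TestSurveyScoreFixture:
    """Checks against the packaged 100-assembly survey score table."""

    def test_recomputed_fractions_match_printed_two_decimals(self, printed_scores):
        frac = necromass_fraction(printed_scores["cell"],
                                  printed_scores["photosynthate"])
        rounded = [round_fraction(f) for f in frac]
        assert rounded == list(printed_scores["cell_fraction"])

    def test_grand_totals_within_rounding_slack(self, printed_scores):
        assert printed_scores["cell"].sum() == pytest.approx(521794.37, abs=1.0)
        assert printed_scores["photosynthate"].sum() == pytest.approx(227434.98, abs=1.0)

    def test_twenty_assemblies_below_half(self, printed_scores):
        counts = threshold_counts(printed_scores)
        assert counts["n_fraction_below"] == 20

    def test_photosynthate_share_counts(self, printed_scores):
        # the survey narrative quotes 45 assemblies above a 30% photosynthate
        # share (34 sediments); recomputing from the printed table itself
        # gives 43 and 33
        counts = threshold_counts(printed_scores)
        assert counts["n_photosynthate_share_above"] == 43
        assert counts["n_photosynthate_share_above_sediment"] == 33
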