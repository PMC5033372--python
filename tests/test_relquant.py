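"""ddCT arithmetic, fold normalization, detectability and abundance bins."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import selenoqpcr as sq


def _ct_frame(rows):
    return pd.DataFrame(rows, columns=["animal_id", "phase", "group",
                                       "region", "gene", "ct"])


def _one_stratum(ctrl_dct, pd_dct, gene="Gpx1", region="cortex",
                 phase="discovery", ref_ct=20.0):
    rows = []
    for i, d in enumerate(ctrl_dct):
        rows += [(f"c{i}", phase, "control", region, "Actb", ref_ct),
                 (f"c{i}", phase, "control", region, gene, ref_ct + d)]
    for i, d in enumerate(pd_dct):
        rows += [(f"p{i}", phase, "PD", region, "Actb", ref_ct),
                 (f"p{i}", phase, "PD", region, gene, ref_ct + d)]
    return _ct_frame(rows)


class TestDeltaCT:
    @pytest.mark.parametrize("gene_ct,ref_ct,expected", [
        (25.0, 20.0, 5.0), (20.0, 20.0, 0.0), (18.3, 20.0, -1.7),
    ])
    def test_arithmetic(self, gene_ct, ref_ct, expected):
        ct = _ct_frame([("a1", "discovery", "control", "pons", "Gpx1", gene_ct),
                        ("a1", "discovery", "control", "pons", "Actb", ref_ct)])
        out = sq.delta_ct(ct, "Actb")
        assert out["delta_ct"].iloc[0] == pytest.approx(expected)

    def test_missing_reference_names_animal(self):
        ct = _ct_frame([("a7", "discovery", "control", "pons", "Gpx1", 24.0)])
        with pytest.raises(ValueError, match="a7"):
            sq.delta_ct(ct, "Actb")

    def test_nd_target_propagates(self):
        ct = _ct_frame([("a1", "discovery", "control", "pons", "Selv", np.nan),
                        ("a1", "discovery", "control", "pons", "Actb", 20.0)])
        out = sq.delta_ct(ct, "Actb")
        assert math.isnan(out["delta_ct"].iloc[0])


class TestNormalizedFolds:
    def test_known_shift(self):
        ct = _one_stratum([5, 5, 5], [6, 6, 6])
        folds = sq.normalized_folds(sq.delta_ct(ct, "Actb"))
        assert folds.loc[folds.group == "control", "fold"].tolist() == \
            pytest.approx([1, 1, 1])
        assert folds.loc[folds.group == "PD", "fold"].tolist() == \
            pytest.approx([0.5, 0.5, 0.5])

    def test_matches_direct_ddct_oracle(self):
        """Agrees with an independently coded 2^-ddCT derivation."""
        ctrl, pdg = [4.8, 5.1, 5.3, 5.0], [5.9, 6.2, 6.0, 6.3]
        folds = sq.normalized_folds(sq.delta_ct(_one_stratum(ctrl, pdg), "Actb"))
        # oracle: 2^-(dct - mean ctrl dct), then divide by control mean
        b = sum(ctrl) / len(ctrl)
        raw_c = [2 ** -(d - b) for d in ctrl]
        raw_p = [2 ** -(d - b) for d in pdg]
        mc = sum(raw_c) / len(raw_c)
        expect_pd_mean = (sum(raw_p) / len(raw_p)) / mc
        got = folds.loc[folds.group == "PD", "fold"].mean()
        assert got == pytest.approx(expect_pd_mean, rel=1e-12)

    def test_empty_control_group_rejected(self):
        ct = _ct_frame([("p1", "discovery", "PD", "pons", "Gpx1", 24.0),
                        ("p1", "discovery", "PD", "pons", "Actb", 20.0),
                        ("p2", "discovery", "PD", "pons", "Gpx1", 24.2),
                        ("p2", "discovery", "PD", "pons", "Actb", 20.0)])
        with pytest.raises(ValueError, match="no control"):
            sq.normalized_folds(sq.delta_ct(ct, "Actb"))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-3, 8), min_size=2, max_size=6),
           st.lists(st.floats(-3, 8), min_size=1, max_size=6),
           st.floats(-5, 5))
    def test_control_mean_one_and_shift_invariance(self, ctrl, pdg, shift):
        """mean(control folds) == 1 by construction, and adding a constant
        to every CT of an animal x region (reference included) changes
        nothing (reference-gene cancellation)."""
        ct = _one_stratum(ctrl, pdg)
        folds = sq.normalized_folds(sq.delta_ct(ct, "Actb"))
        assert folds.loc[folds.group == "control", "fold"].mean() == \
            pytest.approx(1.0, abs=1e-12)
        assert (folds["fold"] > 0).all()
        shifted = ct.copy()
        shifted["ct"] = shifted["ct"] + shift  # same animal-level offset
        folds2 = sq.normalized_folds(sq.delta_ct(shifted, "Actb"))
        assert np.allclose(folds["fold"], folds2["fold"], rtol=1e-9)


class TestPercentChange:
    @pytest.mark.parametrize("pd_mean,expected", [
        (0.446, -55.4), (1.169, 16.9), (1.0, 0.0),
    ])
    def test_reads_off_pd_mean(self, pd_mean, expected):
        assert sq.percent_change([1.0, 1.0], [pd_mean]) == \
            pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sq.percent_change([1.0], [])


class TestDetectability:
    def _records(self, cts):
        return pd.DataFrame({"ct": cts})

    def test_all_nd_is_not_detected(self):
        assert not sq.detectability(self._records([np.nan] * 6))

    def test_moderate_ct_is_detected(self):
        assert sq.detectability(self._records([24.0] * 6))

    def test_nd_fraction_rule(self):
        cts = [np.nan] * 6 + [24.0] * 4  # 60% ND
        assert not sq.detectability(self._records(cts), max_nd_fraction=0.5)

    def test_high_mean_ct_rule(self):
        assert not sq.detectability(self._records([36.0] * 4), max_ct=35.0)


class TestAbundance:
    @pytest.mark.parametrize("gene_offset,exp,bin_", [
        (0.0, 1.0, "medium"), (4.0, 0.0625, "barely_detectable"),
        (-1.0, 2.0, "high"),
    ])
    def test_index_and_bin(self, gene_offset, exp, bin_):
        rows = []
        for i in range(3):
            rows += [(f"c{i}", "discovery", "control", "pons", "Actb", 20.0),
                     (f"c{i}", "discovery", "control", "pons", "Gpx1",
                      20.0 + gene_offset)]
        rec = sq.abundance_index(pd.DataFrame(
            rows, columns=["animal_id", "phase", "group", "region", "gene",
                           "ct"]), "Gpx1", "pons", "Actb")
        assert rec.exp_index == pytest.approx(exp)
        assert rec.bin == bin_

    def test_undetected_gene_scores_zero(self):
        rows = [("c0", "discovery", "control", "pons", "Actb", 20.0),
                ("c0", "discovery", "control", "pons", "Selv", np.nan)]
        rec = sq.abundance_index(pd.DataFrame(
            rows, columns=["animal_id", "phase", "group", "region", "gene",
                           "ct"]), "Selv", "pons", "Actb")
        assert rec.exp_index == 0.0
        assert rec.bin == "barely_detectable"

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0, 5), st.floats(0, 5))
    def test_bin_monotonicity(self, a, b):
        order = ["barely_detectable", "low", "medium", "high"]
        lo, hi = sorted([a, b])
        assert order.index(sq.assign_bin(lo)) <= order.index(sq.assign_bin(hi))

    def test_boundary_bins(self):
        assert sq.assign_bin(1.0) == "medium"   # high means exceeding reference
        assert sq.assign_bin(0.1) == "low"
        assert sq.assign_bin(0.5) == "medium"
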