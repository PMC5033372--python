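"""Per-phase testing, tier classification, repeatability gate, pooling."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import selenoqpcr as sq
from selenoqpcr.stats import CATEGORIES, ChangeLabel


def t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test, coded independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
        / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * sps.t.sf(abs(t), na + nb - 2)


class TestPhaseTest:
    def test_identical_groups_give_p_one(self):
        assert sq.phase_test([1.0, 1.2], [1.0, 1.2]) == pytest.approx(1.0)

    def test_matches_pooled_variance_oracle(self):
        a, b = [0.9, 1.1, 1.0, 1.0], [0.5, 0.6, 0.55]
        assert sq.phase_test(a, b) == pytest.approx(t_oracle(a, b),
                                                    abs=1e-10)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.1, 3), min_size=2, max_size=8),
           st.lists(st.floats(0.1, 3), min_size=2, max_size=8))
    def test_oracle_agreement_random(self, a, b):
        got = sq.phase_test(a, b)
        if math.isnan(got):  # degenerate variance
            assert np.var(a) + np.var(b) < 1e-12
        else:
            assert got == pytest.approx(t_oracle(a, b), abs=1e-10)

    def test_degenerate_variance_not_assessable(self):
        assert math.isnan(sq.phase_test([1.0, 1.0], [0.5, 0.5]))
        assert math.isnan(sq.phase_test([1.0], [0.5, 0.6]))


class TestClassifier:
    @pytest.mark.parametrize("pct,p,cat,direction", [
        (-20.6, 0.04, "significant", "down"),   # p < alpha wins
        (-18.8, 0.11, "trend_15_20", "down"),
        (-21.4, 0.17, "trend_gt20", "down"),
        (8.0, 0.20, "no_change", "none"),       # below the trend floor
        (10.0, 0.50, "no_change", "none"),      # floor must be exceeded
        (12.0, math.nan, "trend_10_15", "up"),  # p not assessable
        (16.9, 0.01, "significant", "up"),
    ])
    def test_examples(self, pct, p, cat, direction):
        lab = sq.classify_change(pct, p)
        assert (lab.category, lab.direction) == (cat, direction)

    def test_annotation_classification(self):
        assert sq.classify_from_annotation(-20.6, "<0.05").category == \
            "significant"
        assert sq.classify_from_annotation(-21.4, "=0.17").category == \
            "trend_gt20"

    def test_exhaustive_and_mutually_exclusive_over_grid(self):
        """Every (percent, p) pair maps to exactly one valid category and
        the tier brackets partition |percent|."""
        pcts = np.concatenate([np.linspace(-60, 60, 121),
                               [-20.0, -15.0, -10.0, 10.0, 15.0, 20.0]])
        ps = [0.001, 0.049, 0.05, 0.2, 0.9, math.nan]
        for pct, p in itertools.product(pcts, ps):
            lab = sq.classify_change(pct, p)
            assert lab.category in CATEGORIES
            sig = (not math.isnan(p)) and p < 0.05 and pct != 0
            if sig:
                assert lab.category == "significant"
            else:
                a = abs(pct)
                expect = ("trend_gt20" if a > 20 else
                          "trend_15_20" if a > 15 else
                          "trend_10_15" if a > 10 else "no_change")
                assert lab.category == expect
            assert lab.direction == ("up" if pct > 0 and lab.changed else
                                     "down" if pct < 0 and lab.changed else
                                     "none")


class TestRepeatability:
    sd = ChangeLabel("significant", "down")
    su = ChangeLabel("significant", "up")
    td = ChangeLabel("trend_10_15", "down")
    tu = ChangeLabel("trend_gt20", "up")
    nc = ChangeLabel("no_change", "none")

    @pytest.mark.parametrize("a,b,expected", [
        ("sd", "sd", True), ("sd", "td", True), ("tu", "tu", True),
        ("tu", "td", False), ("sd", "nc", False), ("nc", "nc", False),
        ("su", "sd", False),
    ])
    def test_rule(self, a, b, expected):
        assert sq.is_repeatable(getattr(self, a), getattr(self, b)) is expected


class TestCombined:
    def test_pooled_n_is_sum_of_phases(self):
        rng = np.random.default_rng(0)
        dc, dp = rng.normal(1, .1, 4), rng.normal(.6, .1, 4)
        rc, rp = rng.normal(1, .1, 3), rng.normal(.6, .1, 3)
        out = sq.combined_analysis(dc, dp, rc, rp, repeatable=True)
        assert (out.n_control, out.n_pd) == (7, 7)

    def test_gate_blocks_combined(self):
        out = sq.combined_analysis([1, 1.1], [0.5, 0.6], [1, 1.1],
                                   [0.5, 0.6], repeatable=False)
        assert out is None

    def test_identical_groups_no_change(self):
        out = sq.combined_analysis([1.0, 1.2], [1.0, 1.2], [0.9, 1.1],
                                   [0.9, 1.1], repeatable=True)
        assert out.percent_change == pytest.approx(0.0)
        assert out.label.category == "no_change"


def _two_phase_table(fold_d, fold_r, sd=0.0, seed=0, gene="Gpx1",
                     region="cortex"):
    sc = sq.Scenario(genes=(gene, "Actb"), regions=(region,),
                     folds={(gene, region, "discovery"): fold_d,
                            (gene, region, "replication"): fold_r},
                     ct_noise_sd=sd, seed=seed)
    return sq.simulate_ct(sc)


class TestRunTwoPhase:
    def test_noise_free_planted_fold(self, panel):
        ct = _two_phase_table(0.6, 0.6)
        res = sq.run_two_phase(ct, _mini_panel())
        r = {x.gene: x for x in res}["Gpx1"]
        assert r.repeatable
        assert r.combined.percent_change == pytest.approx(-40.0, abs=1e-9)
        assert r.combined.n_control == 7

    def test_direction_discordant_strata_blocked(self):
        """Opposite planted directions in the two phases never yield a
        combined result, however large the pooled effect."""
        ct = _two_phase_table(0.5, 2.0)
        res = sq.run_two_phase(ct, _mini_panel())
        r = {x.gene: x for x in res}["Gpx1"]
        assert not r.repeatable
        assert r.combined is None
        assert r.final_label == "no_change"

    def test_missing_phase_not_assessable(self):
        ct = _two_phase_table(0.6, 0.6)
        ct = ct[ct["phase"] == "discovery"].reset_index(drop=True)
        res = sq.run_two_phase(ct, _mini_panel())
        r = {x.gene: x for x in res}["Gpx1"]
        assert r.status == "not_assessable"
        assert r.combined is None

    def test_sign_symmetry(self):
        """Inverting the planted fold flips every direction and preserves
        the changed/unchanged verdict (effects kept clear of the tier
        boundaries, where a reciprocal legitimately changes bracket)."""
        for fold in (0.6, 0.8):
            a = {x.gene: x for x in sq.run_two_phase(
                _two_phase_table(fold, fold), _mini_panel())}["Gpx1"]
            b = {x.gene: x for x in sq.run_two_phase(
                _two_phase_table(1 / fold, 1 / fold), _mini_panel())}["Gpx1"]
            assert a.combined.label.direction == "down"
            assert b.combined.label.direction == "up"
            assert a.combined.label.changed == b.combined.label.changed

    def test_gate_soundness_random_tables(self):
        """Combined results exist iff the gate passed, over noisy tables."""
        rng = np.random.default_rng(7)
        checked_blocked = 0
        for i in range(30):
            fold_d, fold_r = rng.uniform(0.4, 1.6, size=2)
            ct = _two_phase_table(fold_d, fold_r, sd=0.4, seed=int(i))
            r = {x.gene: x for x in sq.run_two_phase(ct, _mini_panel())}["Gpx1"]
            assert (r.combined is not None) == r.repeatable
            checked_blocked += (not r.repeatable)
        assert checked_blocked > 0


def _mini_panel():
    from selenoqpcr.panel import GenePanel, PanelEntry
    return GenePanel((PanelEntry("Gpx1", "Gpx1", "GPX", "A", "T"),
                      PanelEntry("Th", "Th", "marker", "A", "T"),
                      PanelEntry("Actb", "b-actin", "reference", "A", "T")),
                     reference_gene="Actb", marker_gene="Th")
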