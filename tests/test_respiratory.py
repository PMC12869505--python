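"""Plethysmography indices, session averaging and the mixed model."""

import numpy as np
import pandas as pd
import pytest

from myophen.respiratory import (
    BreathRecord,
    breath_indices,
    fit_wbp_model,
    session_average,
    summarize_sessions,
)
from myophen.synth import make_breath_table, null_breath_design


def _records(n=60, **overrides):
    base = dict(Ti=0.08, Te=0.12, tR=0.06, TV=0.2, f=300.0, PIF=3.0, PIP=1.0, PEP=0.9)
    base.update(overrides)
    return pd.DataFrame([base] * n)


class TestBreathIndices:
    def test_zero_when_te_equals_tr(self):
        assert breath_indices(0.1, 0.1, 1.3, 1.1) == (0.0, 0.0)

    def test_substitution(self):
        pause, penh = breath_indices(0.2, 0.1, 0.7, 0.7)
        assert pause == pytest.approx(1.0) and penh == pytest.approx(1.0)

    def test_dimensionless_invariance(self):
        p1, h1 = breath_indices(0.2, 0.08, 0.9, 1.1)
        p2, h2 = breath_indices(0.2 * 3, 0.08 * 3, 0.9, 1.1)  # rescale times
        p3, h3 = breath_indices(0.2, 0.08, 0.9 * 5, 1.1 * 5)  # rescale pressures
        assert p1 == pytest.approx(p2) and h1 == pytest.approx(h2)
        assert h1 == pytest.approx(h3)

    def test_guards(self):
        with pytest.raises(ValueError):
            breath_indices(0.2, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            breath_indices(0.2, 0.1, 1.0, 0.0)

    def test_record_validation(self):
        with pytest.raises(ValueError, match="tR"):
            BreathRecord(Ti=0.1, Te=0.1, tR=0.2, TV=0.2, f=300, PIF=3, PIP=1, PEP=0.9)


class TestSessionAverage:
    def test_constant_records(self):
        s = session_average(_records(60), body_weight=25.0)
        assert s.means["Te"] == pytest.approx(0.12)
        assert s.pause == pytest.approx(1.0)
        assert s.penh == pytest.approx(0.9)
        assert s.tv_per_weight == pytest.approx(0.2 / 25.0)
        assert s.log_penh == pytest.approx(np.log(0.9))

    def test_pause_zero_when_mean_te_equals_mean_tr(self):
        # Te values straddle the constant tR so that mean(Te) == mean(tR):
        # the session pause (computed on means) is exactly zero
        df = _records(60)
        df["Te"] = [0.08] * 30 + [0.04] * 30
        df["tR"] = 0.06
        s = session_average(df, body_weight=25.0)
        assert s.pause == pytest.approx(0.0)

    def test_permutation_invariance(self, rng):
        df = _records(60)
        df["Te"] = rng.uniform(0.1, 0.2, 60)
        df["tR"] = df["Te"] * 0.5
        shuffled = df.sample(frac=1.0, random_state=1)
        a = session_average(df, 25.0)
        b = session_average(shuffled, 25.0)
        assert a.pause == pytest.approx(b.pause)
        assert a.penh_breathwise == pytest.approx(b.penh_breathwise)

    def test_warns_on_unexpected_count(self):
        with pytest.warns(UserWarning, match="expected 60"):
            session_average(_records(59), 25.0)


class TestGeneratorAndSummary:
    def test_sixty_rows_per_session_and_zero_noise_means(self):
        t = make_breath_table(n_mice=2, noise_cv=0.0, seed=0)
        counts = t.groupby(["mouse", "age_months"]).size()
        assert (counts == 60).all()
        assert t["Te"].nunique() == 1 and t["Te"].iloc[0] == pytest.approx(0.12)
        assert (t["tR"] <= t["Te"] + 1e-12).all()

    def test_determinism(self):
        a = make_breath_table(n_mice=2, seed=5)
        b = make_breath_table(n_mice=2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_summary_shape(self):
        t = make_breath_table(n_mice=2, seed=1)
        sess = summarize_sessions(t)
        assert len(sess) == 2 * 6 * 2  # mice * (genotype x sex) * ages
        assert {"pause", "penh", "log_penh", "tv_per_weight"} <= set(sess.columns)


class TestWbpModel:
    def test_noiseless_recovery(self):
        design = null_breath_design()
        for s in ("F", "M"):
            design[("HOM", s, 12)] = dict(design[("HOM", s, 12)], tR=0.06 * 1.3)
        t = make_breath_table(n_mice=3, design=design, noise_cv=0.0, seed=0)
        sess = summarize_sessions(t)
        res = fit_wbp_model(sess, "tR")
        tab = res["table"].set_index("term")
        coef = tab.loc["C(age_months)[T.12.0]:C(genotype)[T.HOM]", "coef"]
        assert coef == pytest.approx(0.06 * 0.3, abs=1e-6)

    def test_genotype_encoding_invariance(self):
        t = make_breath_table(n_mice=3, seed=2)
        sess = summarize_sessions(t)
        res1 = fit_wbp_model(sess, "tR")
        relabel = {"WT": "g3_WT", "HET": "g1_HET", "HOM": "g2_HOM"}
        sess2 = sess.assign(genotype=sess["genotype"].map(relabel))
        res2 = fit_wbp_model(sess2, "tR")
        f1 = np.sort(np.asarray(res1["model"].fittedvalues))
        f2 = np.sort(np.asarray(res2["model"].fittedvalues))
        np.testing.assert_allclose(f1, f2, atol=1e-6)

    def test_single_age_falls_back_to_ols(self):
        t = make_breath_table(n_mice=3, design=null_breath_design(ages=(6,)), seed=3)
        sess = summarize_sessions(t)
        with pytest.warns(UserWarning, match="OLS"):
            res = fit_wbp_model(sess, "tR")
        assert "table" in res

    def test_excluded_parameter_rejected(self):
        t = make_breath_table(n_mice=2, seed=4)
        sess = summarize_sessions(t)
        with pytest.raises(ValueError, match="excluded"):
            fit_wbp_model(sess, "EIP")

    def test_holm_family_is_whole_table(self):
        t = make_breath_table(n_mice=3, seed=6)
        sess = summarize_sessions(t)
        tab = fit_wbp_model(sess, "penh")["table"]
        assert (tab["p_holm"] >= tab["p_raw"] - 1e-12).all()
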