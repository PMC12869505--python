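"""Two-phase growth model, phase-wise regressions, grip and organ ratios."""

import numpy as np
import pandas as pd
import pytest

from myophen.growth import (
    fit_breakpoint,
    fit_phase_models,
    grip_normalize,
    relative_weight,
)
from myophen.synth import make_growth_table


class TestBreakpoint:
    def test_noise_free_recovery(self):
        df = make_growth_table(noise_sd=0.0, animal_sd=0.0, breakpoint=3.0, seed=1)
        fit = fit_breakpoint(df, n_boot=0)
        assert fit.breakpoint == pytest.approx(3.0, abs=0.051)
        assert not fit.no_breakpoint

    def test_single_slope_flags_no_breakpoint(self):
        ages = np.tile(np.arange(1, 13), 6)
        df = pd.DataFrame(
            {
                "mouse": np.repeat([f"m{i}" for i in range(6)], 12),
                "age_months": ages.astype(float),
                "weight_g": 10 + 2.0 * ages,
            }
        )
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_breakpoint(df, n_boot=0)
        assert fit.no_breakpoint

    def test_shift_invariance(self):
        df = make_growth_table(seed=2)
        f1 = fit_breakpoint(df, n_boot=0)
        df2 = df.assign(weight_g=df["weight_g"] + 100.0)
        f2 = fit_breakpoint(df2, n_boot=0)
        assert f1.breakpoint == pytest.approx(f2.breakpoint, abs=1e-9)
        assert f1.slope1 == pytest.approx(f2.slope1)

    def test_ci_and_determinism(self):
        df = make_growth_table(seed=3)
        f1 = fit_breakpoint(df, n_boot=200, seed=9)
        f2 = fit_breakpoint(df, n_boot=200, seed=9)
        assert f1.breakpoint_ci == f2.breakpoint_ci
        lo, hi = f1.breakpoint_ci
        assert lo <= f1.breakpoint <= hi

    def test_ci_width_shrinks_with_n(self):
        widths = {}
        for n in (20, 80):
            # n animals total across the 6 genotype x sex cells
            df = make_growth_table(n_per_group=max(1, n // 6), seed=4)
            f = fit_breakpoint(df, n_boot=200, seed=5)
            widths[n] = f.breakpoint_ci[1] - f.breakpoint_ci[0]
        assert widths[80] <= widths[20]

    def test_phase_slopes_match_per_phase_refits(self):
        df = make_growth_table(noise_sd=0.0, animal_sd=0.0, seed=6)
        sub = df[(df.genotype == "WT") & (df.sex == "M")]
        fit = fit_breakpoint(sub, n_boot=0)
        before = sub[sub.age_months <= fit.breakpoint]
        after = sub[sub.age_months > fit.breakpoint]
        s1 = np.polyfit(before.age_months, before.weight_g, 1)[0]
        s2 = np.polyfit(after.age_months, after.weight_g, 1)[0]
        assert fit.slope1 == pytest.approx(s1, rel=1e-6)
        assert fit.slope2 == pytest.approx(s2, rel=1e-3)


class TestPhaseModels:
    def test_zero_noise_exact_slopes(self):
        df = make_growth_table(noise_sd=0.0, animal_sd=0.0, seed=7)
        tab = fit_phase_models(df, 2.2, "before", per_sex=True)
        male = tab[tab.subset == "M"].set_index("term")
        assert male.loc["Age", "coef"] == pytest.approx(8.0, abs=1e-8)
        assert male.loc["Age:Genotype[T.HET]", "coef"] == pytest.approx(-2.5, abs=1e-8)

    def test_wt_faster_growth_detected(self):
        df = make_growth_table(seed=8)
        tab = fit_phase_models(df, 2.2, "before", per_sex=True)
        male = tab[tab.subset == "M"].set_index("term")
        row_p = male.loc["Age:Genotype[T.HET]", "p_holm"]
        assert male.loc["Age:Genotype[T.HET]", "coef"] < 0
        assert row_p < 0.05

    def test_null_genotype_not_flagged(self):
        slopes = {(g, s): (7.0, 0.5) for g in ("WT", "HET", "HOM") for s in ("M", "F")}
        hits, terms = 0, 0
        for seed in range(10):
            df = make_growth_table(slopes=slopes, seed=100 + seed)
            tab = fit_phase_models(df, 2.2, "before")
            geno = tab[tab.term.str.contains("Genotype")]
            hits += (geno["p_raw"] < 0.05).sum()
            terms += len(geno)
        assert hits / terms < 0.15

    def test_small_genotype_dropped(self):
        df = make_growth_table(n_per_group=3, seed=9)
        df = df[~((df.genotype == "HOM") & (df.mouse != "HOM_F_00"))]
        with pytest.warns(UserWarning, match="dropped"):
            tab = fit_phase_models(df, 2.2, "before")
        assert not tab.term.str.contains("HOM").any()


class TestGripAndOrgans:
    def test_grip_arithmetic(self):
        assert grip_normalize([200.0] * 10, 25.0) == pytest.approx(8.0)
        assert grip_normalize([100.0, 300.0], 25.0) == pytest.approx(8.0)

    def test_grip_permutation_and_exclusion(self, rng):
        r = rng.uniform(150, 250, 10)
        assert grip_normalize(r, 30.0) == pytest.approx(grip_normalize(r[::-1], 30.0))
        with pytest.warns(UserWarning, match="non-positive"):
            v = grip_normalize([200.0, -5.0, 200.0], 25.0)
        assert v == pytest.approx(8.0)

    def test_relative_weight(self):
        assert relative_weight(1.0, 25.0, 0.4) == (pytest.approx(0.04), pytest.approx(2.5))
        assert relative_weight(25.0, 25.0, 0.4)[0] == pytest.approx(1.0)
        a = relative_weight(1.0, 25.0, 0.4)
        b = relative_weight(3.0, 75.0, 1.2)
        assert a == (pytest.approx(b[0]), pytest.approx(b[1]))
        with pytest.raises(ValueError):
            relative_weight(1.0, 0.0, 0.4)


class TestGenerator:
    def test_row_count_and_determinism(self):
        df = make_growth_table(n_per_group=2, seed=1)
        assert len(df) == 12 * 2 * 6
        pd.testing.assert_frame_equal(df, make_growth_table(n_per_group=2, seed=1))

    def test_zero_noise_exact_piecewise(self):
        df = make_growth_table(noise_sd=0.0, breakpoint=2.2, seed=2)
        one = df[df.mouse == "WT_M_00"].sort_values("age_months")
        w = one.weight_g.to_numpy()
        a = one.age_months.to_numpy()
        # second differences vanish away from the breakpoint
        assert np.allclose(np.diff(w[a > 3], 2), 0, atol=1e-9)
        assert np.allclose(np.diff(w[a <= 2], 2), 0, atol=1e-9)

    def test_breakpoint_range_validated(self):
        with pytest.raises(ValueError, match="breakpoint"):
            make_growth_table(breakpoint=0.5)
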