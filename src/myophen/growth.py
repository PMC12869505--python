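"""Two-phase body-weight growth models, grip strength and organ weights.

Mouse body weight between 1 and 12 months follows a two-phase pattern: a
fast juvenile growth phase followed by a slow adult phase.  The model is a
continuous two-segment ("broken-stick") linear regression

    weight = b0 + b1 * age + b2 * max(age - bp, 0)

whose breakpoint ``bp`` is estimated by profiling the residual sum of
squares over a fine grid (0.05-month resolution) and whose confidence
interval comes from a seeded case-resampling bootstrap over animals.  Each
phase is then analyzed separately with ordinary linear models including
Age x Genotype interactions (cluster-robust by mouse), Holm-adjusted over
the genotype-involving terms.

Also here: grip-strength normalization (mean of ten force readings over
body weight) and relative organ weights (organ/body and organ/brain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import holm

__all__ = [
    "GrowthFit",
    "fit_breakpoint",
    "fit_phase_models",
    "grip_normalize",
    "relative_weight",
]

GRID_STEP = 0.05  # months


@dataclass
class GrowthFit:
    """Fitted two-phase growth model."""

    breakpoint: float  # months
    breakpoint_ci: tuple[float, float]  # percentile bootstrap, months
    intercept: float
    slope1: float  # g/month before the breakpoint
    slope2: float  # g/month after (slope1 + hinge coefficient)
    rss: float
    no_breakpoint: bool  # RSS profile minimized at the grid boundary
    n_boot: int
    grid: np.ndarray | None = None
    profile: np.ndarray | None = None


def _candidate_grid(ages: np.ndarray, step: float) -> np.ndarray:
    """Breakpoint candidates keeping >=2 distinct ages on each side."""
    uniq = np.unique(ages)
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct ages for a two-phase fit")
    lo, hi = uniq[1], uniq[-2]
    grid = np.arange(lo, hi + step / 2, step)
    return np.round(grid, 6)


def _profile_rss(
    age_u: np.ndarray,
    grid: np.ndarray,
    n_j: np.ndarray,
    s_j: np.ndarray,
    yy: float,
):
    """RSS(bp) over the grid from per-unique-age sufficient statistics.

    For each candidate bp the OLS normal equations of the hinge model are
    assembled from age-level moments (the design depends on age only), so a
    full profile costs O(G * m) with m unique ages, independent of n rows.
    Returns (rss array, coefficient array of shape (G, 3)).
    """
    h = np.clip(age_u[None, :] - grid[:, None], 0.0, None)  # (G, m)
    n = n_j.sum()
    sa = (n_j * age_u).sum()
    saa = (n_j * age_u**2).sum()
    sh = h @ n_j
    shh = (h * h) @ n_j
    sah = h @ (n_j * age_u)
    sy = s_j.sum()
    say = (s_j * age_u).sum()
    shy = h @ s_j
    g = grid.size
    A = np.empty((g, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = sa
    A[:, 0, 2] = A[:, 2, 0] = sh
    A[:, 1, 1] = saa
    A[:, 1, 2] = A[:, 2, 1] = sah
    A[:, 2, 2] = shh
    b = np.empty((g, 3))
    b[:, 0] = sy
    b[:, 1] = say
    b[:, 2] = shy
    # ridge epsilon guards near-singular boundary candidates
    A = A + 1e-9 * np.eye(3)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    rss = yy - np.einsum("gi,gi->g", beta, b)
    return rss, beta


def _refine_min(grid: np.ndarray, rss: np.ndarray, k: int) -> float:
    """Sub-grid profile minimum by parabolic interpolation.

    Without refinement the estimate is quantized to the grid, which
    distorts its sampling distribution (and bootstrap coverage) whenever
    the true breakpoint sits near a grid point.
    """
    if k == 0 or k == grid.size - 1:
        return float(grid[k])
    y0, y1, y2 = rss[k - 1], rss[k], rss[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return float(grid[k])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(grid[k] + shift * (grid[1] - grid[0]))


def _aggregate(ages, y, weights, age_u, inv):
    n_j = np.bincount(inv, weights=weights, minlength=age_u.size)
    s_j = np.bincount(inv, weights=weights * y, minlength=age_u.size)
    yy = float((weights * y * y).sum())
    return n_j, s_j, yy


def fit_breakpoint(
    records: pd.DataFrame,
    *,
    n_boot: int = 500,
    seed: int = 0,
    step: float = GRID_STEP,
    keep_profile: bool = False,
) -> GrowthFit:
    """Estimate the two-phase growth breakpoint with a bootstrap CI.

    ``records`` needs columns ``mouse, age_months, weight_g``.  The RSS of
    the continuous hinge model is profiled over a ``step``-resolution grid
    of candidate breakpoints (candidates keep at least two distinct ages on
    either side); the CI is a percentile interval over ``n_boot`` seeded
    case resamples of animals.  A profile minimized at the grid boundary is
    flagged ``no_breakpoint`` (effectively single-slope data).
    """
    ages = records["age_months"].to_numpy(dtype=float)
    y = records["weight_g"].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("weights must be positive")
    # center the response: the intercept absorbs the mean, and the RSS
    # profile becomes numerically invariant to constant weight shifts
    ybar = y.mean()
    y = y - ybar
    grid = _candidate_grid(ages, step)
    age_u, inv = np.unique(ages, return_inverse=True)
    ones = np.ones_like(y)
    n_j, s_j, yy = _aggregate(ages, y, ones, age_u, inv)
    rss, beta = _profile_rss(age_u, grid, n_j, s_j, yy)
    k = int(np.argmin(rss))
    bp = _refine_min(grid, rss, k)
    # single-line RSS: a hinge model buys nothing on collinear data
    X = np.column_stack([np.ones_like(ages), ages])
    coef_line, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_line = float(((y - X @ coef_line) ** 2).sum())
    flat = (rss_line - rss[k]) <= 1e-9 * max(yy, 1.0)
    no_breakpoint = flat or k in (0, grid.size - 1)
    if no_breakpoint:
        warnings.warn(
            "RSS profile is minimized at the boundary of the candidate grid; "
            "the data may have a single slope (no interior breakpoint)",
            stacklevel=2,
        )
    b0, b1, b2 = beta[k]

    # case-resampling bootstrap over animals
    mice = records["mouse"].to_numpy()
    mouse_u, mouse_inv = np.unique(mice, return_inverse=True)
    m = mouse_u.size
    rng = np.random.default_rng(seed)
    bps = np.empty(n_boot)
    for i in range(n_boot):
        counts = np.bincount(rng.integers(0, m, size=m), minlength=m)
        w = counts[mouse_inv].astype(float)
        if w.sum() == 0:  # pragma: no cover - impossible for m>=1
            bps[i] = bp
            continue
        n_jb, s_jb, yyb = _aggregate(ages, y, w, age_u, inv)
        ok = n_jb > 0
        rss_b, _ = _profile_rss(age_u[ok], grid, n_jb[ok], s_jb[ok], yyb)
        bps[i] = _refine_min(grid, rss_b, int(np.argmin(rss_b)))
    lo, hi = (bp, bp) if n_boot == 0 else np.percentile(bps, [2.5, 97.5])
    return GrowthFit(
        breakpoint=bp,
        breakpoint_ci=(float(lo), float(hi)),
        intercept=float(b0 + ybar),
        slope1=float(b1),
        slope2=float(b1 + b2),
        rss=float(rss[k]),
        no_breakpoint=no_breakpoint,
        n_boot=n_boot,
        grid=grid if keep_profile else None,
        profile=rss if keep_profile else None,
    )


def fit_phase_models(
    records: pd.DataFrame,
    breakpoint: float,
    phase: str,
    *,
    per_sex: bool = False,
) -> pd.DataFrame:
    """Linear model weight ~ Age x Genotype within one growth phase.

    ``phase`` is ``"before"`` (ages in [min, breakpoint], closed on the
    left) or ``"after"`` (ages in (breakpoint, max]).  Standard errors are
    cluster-robust by mouse (repeated measures).  Holm adjustment runs over
    the genotype-involving terms of each (sex-subset) model; genotypes with
    fewer than two animals are dropped with a warning.

    Returns a coefficient frame with columns
    ``subset, term, coef, se, p_raw, p_holm``.
    """
    import statsmodels.formula.api as smf

    if phase == "before":
        sub = records[records["age_months"] <= breakpoint].copy()
    elif phase == "after":
        sub = records[records["age_months"] > breakpoint].copy()
    else:
        raise ValueError("phase must be 'before' or 'after'")
    if sub["age_months"].nunique() < 2:
        raise ValueError("phase contains fewer than 2 distinct ages")

    keep = []
    for g, grp in sub.groupby("genotype"):
        if grp["mouse"].nunique() < 2:
            warnings.warn(f"genotype {g!r} has <2 animals; dropped", stacklevel=2)
        else:
            keep.append(g)
    sub = sub[sub["genotype"].isin(keep)]
    cats = sorted(keep, key=lambda g: {"WT": 0, "HET": 1, "HOM": 2}.get(g, 99))
    subsets = (
        [(s, grp) for s, grp in sub.groupby("sex")] if per_sex else []
    ) + [("pooled", sub)]
    frames = []
    for name, grp in subsets:
        formula = (
            "weight_g ~ age_months * C(genotype, levels=cats)"
            if len(cats) > 1
            else "weight_g ~ age_months"
        )
        res = smf.ols(formula, grp).fit(
            cov_type="cluster", cov_kwds={"groups": grp["mouse"]}
        )
        tab = pd.DataFrame(
            {
                "subset": name,
                "term": [
                    t.replace("C(genotype, levels=cats)", "Genotype")
                    .replace("age_months", "Age")
                    for t in res.params.index
                ],
                "coef": res.params.to_numpy(),
                "se": res.bse.to_numpy(),
                "p_raw": res.pvalues.to_numpy(),
            }
        )
        geno = tab["term"].str.contains("Genotype")
        p_holm = np.full(len(tab), np.nan)
        if geno.any():
            p_holm[geno.to_numpy()] = holm(tab.loc[geno, "p_raw"].to_numpy())
        tab["p_holm"] = p_holm
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def grip_normalize(readings, body_weight: float) -> float:
    """Mean grip force over body weight (g-F / g).

    Ten pull readings per mouse is the standard protocol; non-positive
    readings are excluded with a warning.
    """
    r = np.asarray(readings, dtype=float)
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    bad = r <= 0
    if bad.any():
        warnings.warn(f"excluded {bad.sum()} non-positive reading(s)", stacklevel=2)
        r = r[~bad]
    if r.size == 0:
        raise ValueError("no valid readings")
    return float(r.mean() / body_weight)


def relative_weight(
    organ_weight: float, body_weight: float, brain_weight: float
) -> tuple[float, float]:
    """Organ weight relative to body and to brain weight."""
    if min(organ_weight, body_weight, brain_weight) <= 0:
        raise ValueError("all weights must be positive")
    return organ_weight / body_weight, organ_weight / brain_weight
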