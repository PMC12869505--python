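"""Effect-size-gated nonparametric comparisons for large per-fiber datasets.

Whole-section automation yields thousands of fibers per group, so almost any
between-genotype difference is "statistically significant".  The comparison
machinery here therefore pairs each rank test with the standardized effect
size r = |z| / sqrt(N) and flags a comparison as a *conclusion* only when it
is both significant after Bonferroni-Holm adjustment and relevant (r above a
practical-relevance gate, 0.1 by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GateResult",
    "CvResult",
    "kruskal",
    "pairwise_mwu_holm",
    "mwu_z",
    "holm",
    "cv_ci",
    "nuclei_distribution_compare",
]

ALPHA = 0.05
R_GATE = 0.1


@dataclass
class GateResult:
    """One gated pairwise comparison."""

    comparison: str
    n_a: int
    n_b: int
    statistic: float
    z: float
    p_raw: float
    p_adj: float
    r: float
    significant: bool
    relevant: bool
    conclusion: bool


@dataclass
class CvResult:
    """Coefficient of variation with a bootstrap confidence interval."""

    n: int
    cv: float
    ci: tuple[float, float]
    n_boot: int = field(default=0)


def holm(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def kruskal(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    All-identical data is a degenerate but legal input: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("kruskal needs at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    pooled = np.concatenate(arrs)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


def mwu_z(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns ``(U1, z, p)`` where U1 counts pairs (x_i, y_j) with x_i > y_j
    (ties half), z is the *uncorrected* (no continuity correction) deviate
    and p the two-sided normal p-value.  The plain z is used so that
    r = |z|/sqrt(N) matches the standard rank effect size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    # tie correction to the variance of U
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return float(u1), 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u1), float(z), float(min(p, 1.0))


def pairwise_mwu_holm(
    groups: dict,
    *,
    alpha: float = ALPHA,
    r_gate: float = R_GATE,
) -> pd.DataFrame:
    """All unordered pairwise Mann-Whitney tests, Holm-adjusted, r-gated.

    Parameters
    ----------
    groups
        Mapping label -> 1-d array of values.  Empty groups are skipped
        with a warning.  The Holm family is the set of pairs produced.

    Returns a tidy frame with one :class:`GateResult` row per pair.
    """
    clean = {}
    for k, v in groups.items():
        v = np.asarray(v, dtype=float)
        if v.size == 0:
            warnings.warn(f"group {k!r} is empty; skipped", stacklevel=2)
            continue
        clean[k] = v
    pairs = list(itertools.combinations(clean, 2))
    rows = []
    for a, b in pairs:
        u, z, p = mwu_z(clean[a], clean[b])
        n = clean[a].size + clean[b].size
        rows.append(
            dict(
                comparison=f"{a} vs {b}",
                n_a=clean[a].size,
                n_b=clean[b].size,
                statistic=u,
                z=z,
                p_raw=p,
                r=abs(z) / np.sqrt(n),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["comparison", "n_a", "n_b", "statistic", "z", "p_raw", "r"],
    )
    if df.empty:
        df["p_adj"] = df["significant"] = df["relevant"] = df["conclusion"] = []
        return df
    df["p_adj"] = holm(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    df["relevant"] = df["r"] > r_gate
    df["conclusion"] = df["significant"] & df["relevant"]
    return df


def cv_ci(values, n_boot: int = 2000, seed: int = 0) -> CvResult:
    """Coefficient of variation (sample SD / mean) with a 95% bootstrap CI.

    The CI is a seeded nonparametric percentile bootstrap.  Two groups are
    declared different when their CIs are disjoint; that comparison rule is
    left to the caller.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("cv undefined for non-positive mean")
    cv = v.std(ddof=1) / mean
    if np.ptp(v) == 0:
        return CvResult(n=v.size, cv=0.0, ci=(0.0, 0.0), n_boot=n_boot)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    samples = v[idx]
    means = samples.mean(axis=1)
    sds = samples.std(ddof=1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, np.nan)
    cvs = cvs[np.isfinite(cvs)]
    lo, hi = np.percentile(cvs, [2.5, 97.5])
    return CvResult(n=v.size, cv=float(cv), ci=(float(lo), float(hi)), n_boot=n_boot)


def nuclei_distribution_compare(
    counts: dict,
    *,
    alpha: float = ALPHA,
    r_gate: float = R_GATE,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare per-group internal-nuclei category distributions pairwise.

    ``counts`` maps group label -> vector of fiber counts per category
    (fibers with 0, 1, 2+ internal nuclei).  Each pair is compared by a
    chi-square test on the 2 x k contingency table; the effect size is the
    sqrt(chi2/N) analogue (phi-type), gated at ``r_gate`` like r.  When any
    expected cell falls below 1 a seeded Monte-Carlo permutation p-value is
    used instead and the row is flagged ``exact=True``.

    Per-group category percentages are attached as columns ``pct_<i>``.
    """
    labels = list(counts)
    tabs = {k: np.asarray(v, dtype=float) for k, v in counts.items()}
    k_cat = {v.size for v in tabs.values()}
    if len(k_cat) != 1:
        raise ValueError("all groups must share the category layout")
    for k, v in tabs.items():
        if (v < 0).any() or v.sum() < 1:
            raise ValueError(f"group {k!r} has invalid counts")
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(labels, 2):
        table = np.vstack([tabs[a], tabs[b]])
        # drop categories empty in both groups (zero expected -> undefined)
        table = table[:, table.sum(axis=0) > 0]
        n = table.sum()
        chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
        exact = bool((expected < 1).any())
        if exact:
            p = _perm_chi2_p(table, chi2, n_perm, rng)
        row = dict(
            comparison=f"{a} vs {b}",
            n_a=int(tabs[a].sum()),
            n_b=int(tabs[b].sum()),
            statistic=float(chi2),
            p_raw=float(p),
            r=float(np.sqrt(chi2 / n)),
            exact=exact,
        )
        for i, cat in enumerate(range(tabs[a].size)):
            row[f"pct_{cat}_a"] = 100.0 * tabs[a][i] / tabs[a].sum()
            row[f"pct_{cat}_b"] = 100.0 * tabs[b][i] / tabs[b].sum()
        rows.append(row)
    df = pd.DataFrame(rows)
    df["p_adj"] = holm(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    df["relevant"] = df["r"] > r_gate
    df["conclusion"] = df["significant"] & df["relevant"]
    return df


def _perm_chi2_p(table: np.ndarray, chi2_obs: float, n_perm: int, rng) -> float:
    """Monte-Carlo permutation p for the chi-square statistic."""
    row_tot = table.sum(axis=1).astype(int)
    col_tot = table.sum(axis=0).astype(int)
    hits = 0
    for _ in range(n_perm):
        sim = sps.random_table(row_tot, col_tot).rvs(random_state=rng)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = sps.chi2_contingency(sim + 1e-12, correction=False)[0]
        if stat >= chi2_obs - 1e-9:
            hits += 1
    return (hits + 1) / (n_perm + 1)
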