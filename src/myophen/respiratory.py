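"""Whole-body plethysmography (WBP) indices and longitudinal models.

Unrestrained plethysmography records, every 5 s, a set of breath-timing and
flow/pressure parameters: inspiratory/expiratory time (Ti, Te), relaxation
time (tR), tidal volume (TV), respiratory rate (f), peak inspiratory flow
(PIF) and peak inspiratory/expiratory pressures (PIP, PEP).  Two derived
dimensionless indices summarize expiratory braking:

    pause = (Te - tR) / tR
    Penh  = (PEP / PIP) * pause

Sessions (nominally 60 five-second recordings, i.e. 5 min) are reduced to
arithmetic means; pause and Penh at session level are computed from the
session-mean constituents (the per-breath-then-average variants are also
emitted for comparison).  Longitudinal analysis fits a linear mixed model
with age, sex and genotype (plus two-way interactions) as fixed effects and
a random intercept per mouse, with Bonferroni-Holm adjustment across the
coefficients of one parameter's model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import holm

__all__ = [
    "BreathRecord",
    "RespSession",
    "breath_indices",
    "session_average",
    "summarize_sessions",
    "fit_wbp_model",
    "BREATH_FIELDS",
]

#: per-breath measured quantities, in the breath-table column order
BREATH_FIELDS = ["Ti", "Te", "tR", "TV", "f", "PIF", "PIP", "PEP"]

#: parameters excluded from modelling by default (outlier-prone)
EXCLUDED_PARAMS = ("EIP", "EEP")


@dataclass
class BreathRecord:
    """One 5-s plethysmography recording."""

    Ti: float  # inspiratory time, s
    Te: float  # expiratory time, s
    tR: float  # relaxation time, s
    TV: float  # tidal volume, ml
    f: float  # respiratory rate, breaths/min
    PIF: float  # peak inspiratory flow, ml/s
    PIP: float  # peak inspiratory pressure, a.u.
    PEP: float  # peak expiratory pressure, a.u.

    def __post_init__(self):
        for name in BREATH_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tR > self.Te:
            raise ValueError("relaxation time tR cannot exceed expiratory time Te")


@dataclass
class RespSession:
    """Session-level (5-min) averages for one mouse at one age."""

    mouse: str
    sex: str
    genotype: str
    age: float  # months
    body_weight: float  # g
    n_records: int
    means: dict  # session mean of each BREATH_FIELDS entry
    pause: float
    penh: float
    log_penh: float  # natural log; NaN when Penh <= 0
    tv_per_weight: float  # ml/g
    pause_breathwise: float  # mean of per-breath pause
    penh_breathwise: float  # mean of per-breath Penh
    flags: tuple = ()


def breath_indices(Te: float, tR: float, PEP: float, PIP: float) -> tuple[float, float]:
    """pause = (Te - tR)/tR and Penh = (PEP/PIP) * pause for one breath."""
    if tR <= 0:
        raise ValueError("tR must be positive")
    if PIP <= 0:
        raise ValueError("PIP must be positive")
    pause = (Te - tR) / tR
    penh = (PEP / PIP) * pause
    return pause, penh


def session_average(
    records: pd.DataFrame,
    body_weight: float,
    *,
    mouse: str = "",
    sex: str = "",
    genotype: str = "",
    age: float = np.nan,
    expected_records: int = 60,
    strict: bool = False,
) -> RespSession:
    """Reduce one session's breath rows to a :class:`RespSession`.

    ``records`` must carry the :data:`BREATH_FIELDS` columns.  A session
    with a number of rows other than ``expected_records`` warns (or raises
    when ``strict``); the instrument protocol averages 60 recordings of 5 s.
    """
    if len(records) < 1:
        raise ValueError("session has no records")
    missing = [c for c in BREATH_FIELDS if c not in records.columns]
    if missing:
        raise ValueError(f"missing breath columns: {missing}")
    flags = []
    if len(records) != expected_records:
        msg = f"session has {len(records)} records, expected {expected_records}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
        flags.append("n_records")
    means = {c: float(records[c].mean()) for c in BREATH_FIELDS}
    pause, penh = breath_indices(means["Te"], means["tR"], means["PEP"], means["PIP"])
    pw = (records["Te"] - records["tR"]) / records["tR"]
    penh_w = (records["PEP"] / records["PIP"]) * pw
    if penh <= 0:
        log_penh = float("nan")
        flags.append("penh_nonpositive")
    else:
        log_penh = float(np.log(penh))
    return RespSession(
        mouse=mouse,
        sex=sex,
        genotype=genotype,
        age=age,
        body_weight=float(body_weight),
        n_records=len(records),
        means=means,
        pause=float(pause),
        penh=float(penh),
        log_penh=log_penh,
        tv_per_weight=float(means["TV"] / body_weight),
        pause_breathwise=float(pw.mean()),
        penh_breathwise=float(penh_w.mean()),
        flags=tuple(flags),
    )


def summarize_sessions(
    breaths: pd.DataFrame, *, expected_records: int = 60, strict: bool = False
) -> pd.DataFrame:
    """Collapse a breath-level table to one row per (mouse, age) session.

    Expects columns ``mouse, sex, genotype, age_months, body_weight_g`` plus
    :data:`BREATH_FIELDS`.  Returns a tidy session table with pause, Penh,
    log(Penh) and TV/weight.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore" if not strict else "default")
        for (mouse, age), grp in breaths.groupby(["mouse", "age_months"], sort=True):
            s = session_average(
                grp,
                body_weight=float(grp["body_weight_g"].iloc[0]),
                mouse=str(mouse),
                sex=str(grp["sex"].iloc[0]),
                genotype=str(grp["genotype"].iloc[0]),
                age=float(age),
                expected_records=expected_records,
                strict=strict,
            )
            row = dict(
                mouse=s.mouse,
                sex=s.sex,
                genotype=s.genotype,
                age_months=s.age,
                body_weight_g=s.body_weight,
                n_records=s.n_records,
                pause=s.pause,
                penh=s.penh,
                log_penh=s.log_penh,
                tv_per_weight=s.tv_per_weight,
                pause_breathwise=s.pause_breathwise,
                penh_breathwise=s.penh_breathwise,
                flags=";".join(s.flags),
            )
            row.update(s.means)
            rows.append(row)
    return pd.DataFrame(rows)


def _residual_diagnostics(resid: np.ndarray, fitted: np.ndarray) -> dict:
    resid = np.asarray(resid, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    out = {"normality_p": np.nan, "homoscedasticity_p": np.nan}
    if 3 <= resid.size <= 5000 and np.ptp(resid) > 0:
        out["normality_p"] = float(sps.shapiro(resid).pvalue)
    if resid.size >= 3 and np.ptp(fitted) > 0:
        out["homoscedasticity_p"] = float(
            sps.spearmanr(np.abs(resid), fitted).pvalue
        )
    return out


def fit_wbp_model(
    sessions: pd.DataFrame,
    parameter: str,
    *,
    interactions: bool = True,
    reml: bool = True,
    diagnostics_alpha: float = 0.01,
    robust_fallback: bool = True,
) -> dict:
    """Fit one WBP parameter against age, sex and genotype.

    A linear mixed model with fixed effects age (categorical time point),
    sex and genotype plus, by default, all two-way interactions, and a
    random intercept per mouse.  Returns a dict with keys

    ``table``       coefficient frame (coef, se, z, p_raw, p_holm); the Holm
                    family is all non-intercept fixed effects of this model,
    ``diagnostics`` residual normality / homoscedasticity p-values,
    ``robust``      True when the winsorized-response fallback was used,
    ``model``       the fitted statsmodels results object.

    With a single age per mouse the random intercept is unidentified; the
    fit falls back to ordinary least squares with a warning.
    """
    import statsmodels.formula.api as smf

    if parameter in EXCLUDED_PARAMS:
        raise ValueError(
            f"{parameter} is excluded from modelling by default (outlier-prone); "
            "pass the series to fit_wbp_model under another name to force it"
        )
    df = sessions.dropna(subset=[parameter]).copy()
    if df.empty:
        raise ValueError("no usable sessions")
    df["_y"] = df[parameter].astype(float)
    order = [g for g in ("WT", "HET", "HOM") if g in set(df["genotype"])]
    order += sorted(set(df["genotype"]) - set(order))
    df["genotype"] = pd.Categorical(df["genotype"], categories=order)
    terms = "C(age_months) + C(sex) + C(genotype)"
    rhs = f"({terms})**2" if interactions else terms
    formula = f"_y ~ {rhs}"
    ages_per_mouse = df.groupby("mouse")["age_months"].nunique()
    mixed = (ages_per_mouse > 1).any()

    def _fit(frame):
        if mixed:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(formula, frame, groups=frame["mouse"]).fit(reml=reml)
        else:
            warnings.warn(
                "single age per mouse: random intercept unidentified, "
                "falling back to OLS",
                stacklevel=3,
            )
            res = smf.ols(formula, frame).fit()
        return res

    res = _fit(df)
    diag = _residual_diagnostics(np.asarray(res.resid), np.asarray(res.fittedvalues))
    robust = False
    if robust_fallback and (
        (diag["normality_p"] < diagnostics_alpha)
        or (diag["homoscedasticity_p"] < diagnostics_alpha)
    ):
        lo, hi = np.nanpercentile(df["_y"], [1, 99])
        df["_y"] = df["_y"].clip(lo, hi)
        res = _fit(df)
        diag = _residual_diagnostics(np.asarray(res.resid), np.asarray(res.fittedvalues))
        robust = True

    params = res.params
    bse = res.bse
    pvals = res.pvalues
    names = [
        n
        for n in params.index
        if n != "Intercept" and not n.endswith("Var") and "Group" not in n
    ]
    tab = pd.DataFrame(
        {
            "term": names,
            "coef": [params[n] for n in names],
            "se": [bse[n] for n in names],
            "z": [params[n] / bse[n] if bse[n] > 0 else np.nan for n in names],
            "p_raw": [pvals[n] for n in names],
        }
    )
    tab["p_holm"] = holm(tab["p_raw"].to_numpy())
    return {"table": tab, "diagnostics": diag, "robust": robust, "model": res}
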