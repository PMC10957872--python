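"""Outcome and association statistics for stratified cohort analysis.

Median stratification labels subjects Hi when strictly above the cohort
median (ties go Lo, so "Hi" always means higher than median).  Survival
machinery (Kaplan–Meier, log-rank, Cox proportional hazards with Efron tie
handling) is delegated to lifelines; a seeded label-permutation log-rank
p-value is provided as a small-sample alternative to the chi-square
approximation.  Rank and count tests use exact enumeration at small sample
sizes and the normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxResult",
    "stratify_by_median",
    "km_estimate",
    "logrank_test",
    "logrank_permutation_p",
    "cox_fit",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "fisher_exact",
    "pearson_r",
    "adjust_bh",
]


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float  # months
    event: int  # 1 event observed, 0 censored
    covariates: tuple = ()  # (name, value) pairs

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "time": r.time, "event": r.event}
        row.update(dict(r.covariates))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class KMCurve:
    times: np.ndarray  # ascending event times
    survival: np.ndarray  # S(t) right after each time
    at_risk: np.ndarray  # number at risk just before each time


@dataclass
class CoxResult:
    """Per-covariate partial-likelihood estimates (Efron ties)."""

    coef: dict[str, float]
    se: dict[str, float]
    hr: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    n: int
    n_events: int


def stratify_by_median(values: dict) -> dict:
    """Hi iff strictly above the median; values at the median go Lo."""
    if len(values) < 2:
        raise ValueError("need at least 2 subjects to stratify")
    arr = np.array(list(values.values()), dtype=float)
    med = float(np.median(arr))
    labels = {k: ("Hi" if v > med else "Lo") for k, v in values.items()}
    if all(lab == "Lo" for lab in labels.values()):
        warnings.warn("no value above the median; all subjects labelled Lo", stacklevel=2)
    return labels


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate at the observed event times."""
    if not records:
        raise ValueError("no records")
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    ev_times = np.unique(t[e == 1])
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    at_risk = np.array([(t >= tt).sum() for tt in ev_times])
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk)


def _split(records):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def logrank_test(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]):
    """Two-group log-rank test: (chi-square statistic, p-value), 1 df."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _split(group_a)
    tb, eb = _split(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _logrank_stats_vectorized(times, events, labels):
    """Log-rank chi-square for many label vectors at once.

    ``labels``: (P, n) 0/1 matrix (1 = group A).  Returns length-P array.
    """
    ev_times = np.unique(times[events == 1])
    risk = times[None, :] >= ev_times[:, None]  # (T, n)
    died = (times[None, :] == ev_times[:, None]) & (events[None, :] == 1)
    n_risk = risk.sum(axis=1).astype(float)  # (T,)
    n_died = died.sum(axis=1).astype(float)

    nA_risk = labels @ risk.T  # (P, T)
    oA = labels @ died.T
    eA = n_died * nA_risk / n_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        vA = (
            n_died
            * (nA_risk / n_risk)
            * (1 - nA_risk / n_risk)
            * (n_risk - n_died)
            / np.maximum(n_risk - 1, 1)
        )
    num = (oA - eA).sum(axis=1) ** 2
    den = vA.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2


def logrank_permutation_p(
    group_a: list[SurvivalRecord],
    group_b: list[SurvivalRecord],
    n_permutations: int = 100_000,
    seed: int = 0,
) -> float:
    """Label-permutation p-value for the log-rank statistic.

    Permutes group membership at fixed group sizes and counts permutations
    whose chi-square statistic is at least the observed one (the observed
    labelling is included, so p is never 0).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _split(group_a)
    tb, eb = _split(group_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    n, n_a = len(times), len(ta)
    obs_labels = np.zeros((1, n))
    obs_labels[0, :n_a] = 1
    obs = _logrank_stats_vectorized(times, events, obs_labels)[0]

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n_a]
    perm = np.zeros((n_permutations, n))
    np.put_along_axis(perm, order, 1.0, axis=1)
    stat = _logrank_stats_vectorized(times, events, perm)
    return float((1 + (stat >= obs - 1e-12).sum()) / (1 + n_permutations))


def cox_fit(
    records: list[SurvivalRecord],
    covariate_names: list[str],
    alpha_z: float = 1.96,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling, Wald inference).

    Confidence intervals are exp(coef ± 1.96·SE).  Non-convergence or
    complete separation surfaces as a ValueError with lifelines'
    diagnostics attached.
    """
    df = records_to_frame(records)
    if df["event"].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    for c in covariate_names:
        if c not in df.columns:
            raise KeyError(f"covariate {c!r} missing from records")
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["time", "event", *covariate_names]], "time", "event")
    except Exception as exc:  # ConvergenceError and friends
        raise ValueError(f"Cox fit failed: {exc}") from exc
    coef = cph.params_.to_dict()
    se = cph.standard_errors_.to_dict()
    return CoxResult(
        coef=coef,
        se=se,
        hr={k: float(np.exp(v)) for k, v in coef.items()},
        ci_low={k: float(np.exp(coef[k] - alpha_z * se[k])) for k in coef},
        ci_high={k: float(np.exp(coef[k] + alpha_z * se[k])) for k in coef},
        p=cph.summary["p"].to_dict(),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U; exact enumeration when n+m <= 12."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    method = "exact" if len(x) + len(y) <= 12 else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on pairs (or on differences)."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if len(d) < 1:
        raise ValueError("need at least one pair")
    method = "exact" if len(d) <= 15 else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p on a 2×2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def pearson_r(x, y) -> tuple[float, float]:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need two equal-length samples of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input to Pearson correlation")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
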