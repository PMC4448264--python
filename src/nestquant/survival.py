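"""Cutpoint-based survival analysis: three-group categorization by maximal
log-rank statistic, Kaplan-Meier / log-rank comparison, Cox proportional
hazards, ROC, the Nottingham Prognostic Index, and a Spearman screen.

The cutpoint search mirrors the X-tile procedure: an exhaustive scan over
ordered pairs of candidate cutpoints (midpoints of consecutive distinct
observed values) selecting the pair that maximizes the three-group log-rank
chi-square, subject to a minimum group-size fraction.  The selected
statistic is optimistically biased because it is a maximum over many
correlated tests; an approximate Miller-Siegmund-corrected p-value can be
reported alongside the naive one, but the selection itself is deliberately
uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as sps


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------


def logrank_statistic(times, events, groups) -> float:
    """k-group log-rank chi-square statistic (k-1 degrees of freedom).

    Standard hypergeometric observed-minus-expected form with the usual
    covariance estimator; the quadratic form is evaluated on the first k-1
    groups with a pseudo-inverse for numerical safety.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels, gidx = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")

    event_times = np.unique(times[events == 1])
    if len(event_times) == 0:
        return 0.0
    # at-risk counts per group at each event time, via sorted searchsorted
    n_ij = np.empty((len(event_times), k))
    d_ij = np.zeros((len(event_times), k))
    for g in range(k):
        tg = np.sort(times[gidx == g])
        n_ij[:, g] = len(tg) - np.searchsorted(tg, event_times, side="left")
        te = times[(gidx == g) & (events == 1)]
        idx = np.searchsorted(event_times, te)
        np.add.at(d_ij[:, g], idx, 1.0)
    n_j = n_ij.sum(axis=1)
    d_j = d_ij.sum(axis=1)
    p = n_ij / n_j[:, None]
    O = d_ij.sum(axis=0)
    E = (d_j[:, None] * p).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1), 0.0)
    V = np.diag((c[:, None] * p).sum(axis=0)) - np.einsum("t,ti,tj->ij", c, p, p)
    u = (O - E)[: k - 1]
    v = V[: k - 1, : k - 1]
    return float(u @ np.linalg.pinv(v) @ u)


def logrank_test(times, events, groups) -> tuple[float, float, int]:
    """(chi-square, p-value, df) for the k-group log-rank test."""
    groups = np.asarray(groups)
    k = len(np.unique(groups))
    stat = logrank_statistic(times, events, groups)
    return stat, float(sps.chi2.sf(stat, k - 1)), k - 1


# ---------------------------------------------------------------------------
# cutpoint optimization
# ---------------------------------------------------------------------------


@dataclass
class CategorizationRule:
    """Three-level categorization of a continuous feature."""

    feature: str
    cutpoints: tuple[float, float]  # c1 < c2
    statistic: float = float("nan")
    p_value: float = float("nan")
    corrected_p: float | None = None

    def __post_init__(self) -> None:
        c1, c2 = self.cutpoints
        if not c1 < c2:
            raise ValueError("require c1 < c2")

    def categorize(self, values) -> np.ndarray:
        """Map values to categories 1 (< c1), 2 (c1..c2), 3 (> c2)."""
        v = np.asarray(values, float)
        c1, c2 = self.cutpoints
        return np.where(v < c1, 1, np.where(v <= c2, 2, 3))


def miller_siegmund_p(chi2_stat: float, eps: float) -> float:
    """Approximate corrected p-value for a maximally selected rank statistic.

    Uses the Miller-Siegmund bound for a single optimized cutpoint scanned
    over the (eps, 1-eps) quantile range, applied to the square root of the
    selected chi-square.  For the two-cutpoint search this is a heuristic
    optimism adjustment, not an exact reference distribution.
    """
    z = np.sqrt(max(chi2_stat, 1e-12))
    phi = sps.norm.pdf(z)
    span = np.log(((1 - eps) / eps) ** 2)
    p = phi * (z - 1.0 / z) * span + 4 * phi / z
    return float(np.clip(p, 0.0, 1.0))


def find_cutpoints(
    values,
    times,
    events,
    min_group_frac: float = 0.10,
    feature: str = "feature",
    with_corrected_p: bool = False,
) -> CategorizationRule:
    """Exhaustive search for the cutpoint pair maximizing the 3-group
    log-rank statistic.

    Candidate cutpoints are midpoints between consecutive distinct observed
    values; every group must hold at least ``min_group_frac`` of patients.
    """
    if not (0 < min_group_frac < 1 / 3):
        raise ValueError("min_group_frac must lie in (0, 1/3)")
    v = np.asarray(values, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    n = len(v)
    distinct = np.unique(v)
    if len(distinct) < 3:
        raise ValueError("insufficient spread: need >= 3 distinct values")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    min_n = int(np.ceil(min_group_frac * n))

    best = (-np.inf, None)
    for i in range(len(mids) - 1):
        c1 = mids[i]
        g1 = v < c1
        if g1.sum() < min_n:
            continue
        for j in range(i + 1, len(mids)):
            c2 = mids[j]
            g3 = v > c2
            if g3.sum() < min_n:
                break  # larger j only shrinks group 3
            g2sum = n - g1.sum() - g3.sum()
            if g2sum < min_n:
                continue
            groups = np.where(g1, 1, np.where(g3, 3, 2))
            stat = logrank_statistic(t, e, groups)
            if stat > best[0]:
                best = (stat, (float(c1), float(c2)))
    if best[1] is None:
        raise ValueError("insufficient spread: no feasible cutpoint pair")
    stat, cuts = best
    rule = CategorizationRule(
        feature=feature,
        cutpoints=cuts,
        statistic=stat,
        p_value=float(sps.chi2.sf(stat, 2)),
    )
    if with_corrected_p:
        rule.corrected_p = miller_siegmund_p(stat, min_group_frac)
    return rule


# ---------------------------------------------------------------------------
# Kaplan-Meier / Cox / ROC
# ---------------------------------------------------------------------------


@dataclass
class KMResult:
    """Per-group product-limit estimates with a log-rank comparison."""

    curves: dict  # group -> DataFrame(time, survival)
    medians: dict  # group -> median survival (NaN if never below 0.5)
    statistic: float
    p_value: float
    df: int


def km_logrank(groups, times, events) -> KMResult:
    """Kaplan-Meier curves per group plus the k-group log-rank test."""
    groups = np.asarray(groups)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 nonempty groups")
    curves, medians = {}, {}
    for lab in labels:
        sel = groups == lab
        if sel.sum() == 0:
            raise ValueError(f"group {lab} has no subjects")
        kmf = KaplanMeierFitter().fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        med = kmf.median_survival_time_
        medians[lab] = float(med) if np.isfinite(med) else float("nan")
    stat, p, df = logrank_test(times, events, groups)
    return KMResult(curves=curves, medians=medians, statistic=stat, p_value=p, df=df)


@dataclass
class SurvivalFit:
    """Cox model output: one row per covariate, plus model log-likelihood."""

    table: pd.DataFrame  # coefficient, hazard_ratio, ci_lower, ci_upper, p_value
    log_likelihood: float
    converged: bool = True
    n_events: int = 0


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> SurvivalFit:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Requires at least 10 events and no constant covariate; non-convergence
    raises rather than returning silent output.
    """
    df = records[[duration_col, event_col, *covariates]].copy()
    n_events = int(df[event_col].sum())
    if n_events < 10:
        raise ValueError(f"only {n_events} events; need >= 10")
    for cov in covariates:
        if df[cov].std(ddof=0) <= 0:
            raise ValueError(f"covariate {cov!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary
    table = pd.DataFrame(
        {
            "coefficient": s["coef"],
            "hazard_ratio": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p_value": s["p"],
        }
    )
    return SurvivalFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        n_events=n_events,
    )


def roc_auc(scores, outcome) -> tuple[float, tuple[float, float]]:
    """AUC (pairwise concordance probability) with a Hanley-McNeil 95% CI."""
    scores = np.asarray(scores, float)
    outcome = np.asarray(outcome, int)
    if len(np.unique(outcome)) < 2:
        raise ValueError("outcome must contain both classes")
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score(outcome, scores))
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


# ---------------------------------------------------------------------------
# NPI and Spearman screen
# ---------------------------------------------------------------------------


def npi_score(size_cm: float, ln_stage: int, grade: int) -> float:
    """Nottingham Prognostic Index: 0.2 x size (cm) + LN stage + grade."""
    if ln_stage not in (1, 2, 3):
        raise ValueError("ln_stage must be 1, 2 or 3")
    if grade not in (1, 2, 3):
        raise ValueError("grade must be 1, 2 or 3")
    if size_cm < 0:
        raise ValueError("tumor size must be >= 0")
    return 0.2 * size_cm + ln_stage + grade


def npi_category(score: float) -> int:
    """NPI risk category: 1 (<= 2.8), 2 (2.8 - 4.4), 3 (> 4.4)."""
    if score <= 2.8:
        return 1
    if score <= 4.4:
        return 2
    return 3


def spearman_screen(
    features: pd.DataFrame, grade
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations among features and against grade.

    Returns (rho, p) DataFrames over the feature columns plus a ``grade``
    column; constant vectors yield NaN correlations.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 patients")
    df = features.copy()
    df["grade"] = np.asarray(grade, float)
    cols = df.columns
    rho = pd.DataFrame(np.nan, index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p = sps.spearmanr(x, y)
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval
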