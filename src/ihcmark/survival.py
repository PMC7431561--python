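"""ROC/cutoff dichotomization, Kaplan–Meier, log-rank, Cox regression, and
the nonparametric/categorical group comparisons used around them.

Conventions: follow-up is in months throughout; ``event = 1`` means death,
``0`` censored; the 5-year survival estimate is S(60 months) read off the
Kaplan–Meier curve; dichotomization labels a patient "high" when the score
is at or above the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .errors import InputError

_Z975 = float(stats.norm.ppf(0.975))

#: Reference level used when dummy-encoding each categorical covariate.
DEFAULT_REFERENCES = {
    "sex": "female",
    "stage_group": "early",
    "grade": "well",
    "score_group": "low",
}


# ---------------------------------------------------------------------------
# ROC and cutoff selection
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray   # decreasing; rule: score >= threshold -> test+
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    method: str
    direction: str  # "high_scores_positive" | "low_scores_positive"


def roc_curve(scores, outcome) -> RocResult:
    """ROC points over all distinct thresholds, with trapezoidal AUC.

    ``outcome`` is the binary event of interest (1 = event). The AUC equals
    the Mann–Whitney concordance probability P(score_event > score_no_event)
    with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    if set(np.unique(outcome)) != {0, 1}:
        raise InputError("outcome must contain both classes (0 and 1)")

    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], outcome[order]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    # cumulative counts at each distinct threshold (score >= t -> positive)
    distinct = np.flatnonzero(np.diff(s, append=-np.inf))
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[distinct]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def _sens_spec(scores, outcome, cutoff, direction) -> tuple[float, float]:
    test_pos = (scores >= cutoff) if direction == "high_scores_positive" \
        else (scores < cutoff)
    pos, neg = outcome == 1, outcome == 0
    sens = float(np.count_nonzero(test_pos & pos)) / pos.sum()
    spec = float(np.count_nonzero(~test_pos & neg)) / neg.sum()
    return sens, spec


def select_cutoff(scores, outcome, method: str = "balanced",
                  times=None, events=None,
                  direction: str | None = None) -> CutoffResult:
    """Choose a dichotomization cutoff against a binary outcome.

    Candidate cutoffs are the midpoints between adjacent distinct scores.
    ``balanced`` minimizes |sensitivity - specificity|; ``youden`` maximizes
    sensitivity + specificity - 1; ``logrank_scan`` picks the cutoff whose
    score >= cutoff split minimizes the log-rank p-value (requires ``times``
    and ``events``). Ties break toward the lower cutoff. ``direction``
    states which side of the cutoff counts as a positive test for the
    outcome; by default it is inferred from the AUC (scores higher in the
    event class mean high scores test positive).
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise InputError("all scores equal; no cutoff exists")
    if direction is None:
        auc = roc_curve(scores, outcome).auc
        direction = ("high_scores_positive" if auc >= 0.5
                     else "low_scores_positive")

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best, best_key = None, None
    for c in candidates:
        sens, spec = _sens_spec(scores, outcome, c, direction)
        if method == "balanced":
            key = abs(sens - spec)
        elif method == "youden":
            key = -(sens + spec - 1.0)
        elif method == "logrank_scan":
            if times is None or events is None:
                raise InputError("logrank_scan needs times and events")
            groups = np.where(scores >= c, "high", "low")
            key = logrank([(np.asarray(times)[groups == g],
                            np.asarray(events)[groups == g])
                           for g in ("low", "high")]).p_value
        else:
            raise InputError(f"unknown cutoff method {method!r}")
        if best_key is None or key < best_key - 1e-12:
            best, best_key = (c, sens, spec), key
    cutoff, sens, spec = best
    return CutoffResult(cutoff=float(cutoff), sensitivity=sens,
                        specificity=spec, method=method, direction=direction)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with step-function queries."""

    event_times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray         # S just after each event time
    at_risk: np.ndarray          # subjects at risk at each event time
    n: int
    n_events: int
    median_months: float | None  # None when S never reaches 0.5

    def S_at(self, t: float) -> float:
        """Right-continuous survival probability at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def five_year_survival(self) -> float:
        return self.S_at(60.0)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    At tied times, events precede censorings. The median is the smallest
    time at which S(t) <= 0.5 and is undefined (None) when the curve never
    drops that far — e.g. a fully censored cohort has S(t) = 1 throughout.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise InputError("empty cohort")
    if (times < 0).any():
        raise InputError("negative survival times")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    has_event = tbl["observed"] > 0
    ts = tbl.index.to_numpy(dtype=float)[has_event]
    surv = kmf.survival_function_at_times(ts).to_numpy()
    at_risk = tbl["at_risk"].to_numpy()[has_event]
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return SurvivalCurve(event_times=ts, survival=surv, at_risk=at_risk,
                         n=int(times.size), n_events=int(events.sum()),
                         median_months=median)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank(groups: Sequence[tuple]) -> LogrankResult:
    """K-sample log-rank test with hypergeometric variance at each distinct
    event time; p from chi-square with (k - 1) degrees of freedom."""
    if len(groups) < 2:
        raise InputError("log-rank needs >= 2 groups")
    for i, (t, e) in enumerate(groups):
        if len(np.asarray(t)) == 0:
            raise InputError(f"log-rank group {i} is empty")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e).astype(int) for _, e in groups])
    labels = np.concatenate([np.full(len(np.asarray(t)), i)
                             for i, (t, _) in enumerate(groups)])
    if events.sum() == 0:
        return LogrankResult(statistic=0.0, df=len(groups) - 1, p_value=1.0)
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(statistic=float(res.test_statistic),
                         df=len(groups) - 1, p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs per expanded covariate."""

    table: pd.DataFrame  # index: covariate; HR, ci95_low, ci95_high, p_value
    ties: str
    converged: bool
    n: int
    n_events: int
    warnings: tuple[str, ...] = ()

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hazard_ratio"])


def _design_matrix(cohort: pd.DataFrame, covariates: Sequence[str],
                   references: dict) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        s = cohort[cov]
        if s.dtype.kind in "ifu" and s.nunique() > 2:
            cols[cov] = s.astype(float)
            continue
        levels = [str(v) for v in pd.unique(s.astype(str))]
        ref = references.get(cov, sorted(levels)[0])
        if ref not in levels:
            ref = sorted(levels)[0]
        for lev in sorted(lv for lv in levels if lv != ref):
            cols[f"{cov}[{lev} vs {ref}]"] = (
                s.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def cox_ph(cohort: pd.DataFrame, covariates: Sequence[str],
           duration_col: str = "time_months", event_col: str = "event",
           ties: str = "efron",
           references: dict | None = None) -> CoxResult:
    """Multivariate Cox model via maximum partial likelihood.

    Categorical covariates are dummy-encoded against a stated reference
    level (see :data:`DEFAULT_REFERENCES`); Wald 95% CIs are formed on the
    log-hazard scale and exponentiated. Tie handling is Efron by default,
    Breslow by ``ties="breslow"``.
    """
    if ties not in ("efron", "breslow"):
        raise InputError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    events = cohort[event_col].astype(int)
    if events.sum() == 0:
        raise InputError("no events in cohort; Cox model is undefined")
    refs = {**DEFAULT_REFERENCES, **(references or {})}
    X = _design_matrix(cohort, covariates, refs)
    if X.shape[1] == 0:
        raise InputError("no usable covariates")

    warnings: list[str] = []
    model = PHReg(cohort[duration_col].to_numpy(dtype=float),
                  X.to_numpy(), status=events.to_numpy(), ties=ties)
    res = model.fit(disp=False)
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    converged = bool(np.all(np.isfinite(params)) and np.all(np.isfinite(bse)))
    if converged and (np.abs(params) > 15).any():
        converged = False
        warnings.append("possible complete separation: |log HR| > 15")
    if not converged:
        warnings.append("model did not converge cleanly; estimates flagged")

    z = params / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "hazard_ratio": np.exp(params),
        "ci95_low": np.exp(params - _Z975 * bse),
        "ci95_high": np.exp(params + _Z975 * bse),
        "p_value": pvals,
    }, index=X.columns)
    return CoxResult(table=table, ties=ties, converged=converged,
                     n=len(cohort), n_events=int(events.sum()),
                     warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# Group comparisons (Mann–Whitney / Kruskal–Wallis + Dunn / chi² / Fisher)
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    kind: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    note: str = ""


def _dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn pairwise z-tests on mean ranks, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = (n_total * (n_total + 1) / 12.0
                - tie_term / (12.0 * (n_total - 1)))
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p_raw": p_raw,
                         "p_bonferroni": min(1.0, p_raw * m)})
    return pd.DataFrame(rows)


def compare_groups(values, group_labels=None,
                   kind: str = "mann_whitney") -> GroupComparison:
    """Group comparison tests; all p-values two-sided.

    * ``mann_whitney`` / ``kruskal_wallis_dunn`` take ``values`` plus
      ``group_labels`` (tie-corrected rank tests; Dunn pairwise z-tests
      with Bonferroni adjustment follow Kruskal–Wallis).
    * ``chi_square`` / ``fisher_exact`` take a contingency table in
      ``values``; chi-square switches to Fisher's exact test when any
      expected cell count is below 5 in a 2x2 table.
    """
    if kind in ("mann_whitney", "kruskal_wallis_dunn"):
        values = np.asarray(values, dtype=float)
        labels = np.asarray(group_labels)
        names = list(pd.unique(labels))
        if len(names) < 2:
            raise InputError("need >= 2 groups")
        groups = {g: values[labels == g] for g in names}
        if any(v.size == 0 for v in groups.values()):
            raise InputError("empty group")

        if kind == "mann_whitney":
            if len(names) != 2:
                raise InputError("Mann–Whitney compares exactly 2 groups")
            a, b = (groups[g] for g in names)
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            return GroupComparison(kind=kind, statistic=float(res.statistic),
                                   p_value=float(res.pvalue))
        pooled = np.concatenate(list(groups.values()))
        if np.ptp(pooled) == 0.0:
            return GroupComparison(kind=kind, statistic=0.0, p_value=1.0,
                                   pairwise=_dunn_posthoc(groups),
                                   note="all values identical")
        stat, p = stats.kruskal(*groups.values())
        return GroupComparison(kind=kind, statistic=float(stat),
                               p_value=float(p),
                               pairwise=_dunn_posthoc(groups))

    table = np.asarray(values, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("contingency table must be at least 2x2")
    if kind == "fisher_exact":
        if table.shape != (2, 2):
            raise InputError("Fisher's exact test requires a 2x2 table")
        _, p = stats.fisher_exact(table)
        return GroupComparison(kind=kind, statistic=float("nan"),
                               p_value=float(p))
    if kind == "chi_square":
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any() and table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            return GroupComparison(
                kind="fisher_exact", statistic=float("nan"), p_value=float(p),
                note="expected count < 5; switched to Fisher's exact test")
        note = ("expected count < 5 in a table larger than 2x2; "
                "chi-square retained" if (expected < 5).any() else "")
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(kind="chi_square", statistic=float(stat),
                               p_value=float(p), note=note)
    raise InputError(f"unknown comparison kind {kind!r}")
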