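"""Cohort-level prognostic modelling of a dichotomized biomarker score.

:class:`PrognosisModel` bundles the full patient-level workflow — ROC against
mortality, cutoff selection, dichotomization into low/high expression
groups, Kaplan–Meier curves with log-rank comparison, a multivariate Cox
model, and stage-subgroup re-analysis — behind a ``fit()`` that returns a
:class:`PrognosisResults` carrying the estimates and a ``summary()`` table.

Example
-------
>>> from ihcmark.simulate import CohortSimConfig, generate_cohort
>>> cohort = generate_cohort(CohortSimConfig(), seed=1)
>>> res = PrognosisModel(cohort, score_col="nuclear_pct").fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .survival import (CoxResult, CutoffResult, RocResult, compare_groups,
                       cox_ph, km_estimate, logrank, roc_curve,
                       select_cutoff)

REQUIRED_COHORT_COLUMNS = ("age", "sex", "stage_group", "grade",
                           "time_months", "event")

DEFAULT_COVARIATES = ("age", "sex", "stage_group", "grade")


def validate_cohort(df: pd.DataFrame, score_col: str = "nuclear_pct",
                    min_followup_months: float = 1.0) -> pd.DataFrame:
    """Schema-check a patient table and apply the inclusion rule.

    Patients must survive at least ``min_followup_months`` after surgery
    (default one month ≈ 30 days) to enter the survival analysis; earlier
    deaths reflect perioperative, not oncological, outcome.
    """
    missing = [c for c in (*REQUIRED_COHORT_COLUMNS, score_col)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if (df["time_months"] < 0).any():
        bad = df.index[df["time_months"] < 0][:3].tolist()
        raise SchemaError(f"negative follow-up times at rows {bad}")
    if df["stage_group"].isna().any():
        raise SchemaError("stage_group must not be missing")
    kept = df[(df["time_months"] >= min_followup_months)
              | (df["event"] == 0)].copy()
    return kept


@dataclass
class SubgroupResult:
    """Score-group survival contrast within one stage subgroup."""

    name: str
    n: int
    km_by_group: dict
    logrank_p: float | None
    hazard_ratio: float | None
    ci95: tuple[float, float] | None
    estimable: bool
    reason: str = ""


class PrognosisModel:
    """Prognostic model of one immunohistochemical score in a cohort.

    Parameters
    ----------
    cohort
        Patient table with ``age, sex, stage_group, grade, time_months,
        event`` and the score column.
    score_col
        Score to dichotomize (``nuclear_pct`` in [0, 100] or
        ``cytoplasmic_hscore`` in [0, 300]).
    cutoff
        Fixed cutoff; when None the cutoff is selected from the data with
        ``cutoff_method`` against mortality status.
    cutoff_method
        ``balanced`` (sensitivity ≈ specificity), ``youden`` or
        ``logrank_scan``.
    covariates
        Adjustment covariates for the multivariate Cox model; the score
        group is always included.
    """

    def __init__(self, cohort: pd.DataFrame, score_col: str = "nuclear_pct",
                 cutoff: float | None = None,
                 cutoff_method: str = "balanced",
                 covariates: Sequence[str] = DEFAULT_COVARIATES,
                 ties: str = "efron",
                 min_followup_months: float = 1.0):
        self.cohort = validate_cohort(cohort, score_col,
                                      min_followup_months)
        self.score_col = score_col
        self.cutoff = cutoff
        self.cutoff_method = cutoff_method
        self.covariates = tuple(covariates)
        self.ties = ties

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PrognosisModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "PrognosisResults":
        df = self.cohort
        scores = df[self.score_col].to_numpy(dtype=float)
        outcome = df["event"].to_numpy(dtype=int)
        if outcome.sum() == 0:
            raise InputError("no deaths in cohort; prognosis is undefined")

        roc = roc_curve(scores, outcome)
        if self.cutoff is None:
            cut = select_cutoff(scores, outcome, self.cutoff_method,
                                times=df["time_months"], events=outcome)
        else:
            cut = CutoffResult(cutoff=float(self.cutoff),
                               sensitivity=float("nan"),
                               specificity=float("nan"),
                               method="fixed", direction="supplied")

        df = df.copy()
        df["score_group"] = np.where(scores >= cut.cutoff, "high", "low")
        warnings: list[str] = []

        km, lr_p, cox = self._survival_block(df, warnings)
        subgroups = {name: self._subgroup(df[df["stage_group"] == name],
                                          name)
                     for name in ("early", "late")
                     if (df["stage_group"] == name).any()}
        balance = self._group_balance(df)
        return PrognosisResults(
            model=self, cohort=df, roc=roc, cutoff=cut, km_by_group=km,
            logrank_p=lr_p, cox=cox, subgroups=subgroups,
            group_balance=balance, warnings=tuple(warnings))

    def _survival_block(self, df, warnings):
        counts = df["score_group"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            warnings.append("fewer than 2 patients in a score group; "
                            "survival contrast not estimable")
            km = {g: km_estimate(sub["time_months"], sub["event"])
                  for g, sub in df.groupby("score_group")}
            return km, None, None
        km = {g: km_estimate(sub["time_months"], sub["event"])
              for g, sub in df.groupby("score_group")}
        lr = logrank([(sub["time_months"], sub["event"])
                      for _, sub in df.groupby("score_group")])
        try:
            cox = cox_ph(df, ["score_group", *self.covariates],
                         ties=self.ties)
            warnings.extend(cox.warnings)
        except InputError as exc:
            warnings.append(f"Cox model failed: {exc}")
            cox = None
        return km, lr.p_value, cox

    def _subgroup(self, sub: pd.DataFrame, name: str) -> SubgroupResult:
        counts = sub["score_group"].value_counts()
        km = {g: km_estimate(s["time_months"], s["event"])
              for g, s in sub.groupby("score_group")} if len(sub) else {}
        if len(counts) < 2 or counts.min() < 2 or sub["event"].sum() == 0:
            return SubgroupResult(name=name, n=len(sub), km_by_group=km,
                                  logrank_p=None, hazard_ratio=None,
                                  ci95=None, estimable=False,
                                  reason="fewer than 2 patients per group "
                                         "or no events")
        lr = logrank([(s["time_months"], s["event"])
                      for _, s in sub.groupby("score_group")])
        try:
            cox = cox_ph(sub, ["score_group"], ties=self.ties)
            row = cox.table.iloc[0]
            hr, ci = float(row["hazard_ratio"]), (float(row["ci95_low"]),
                                                  float(row["ci95_high"]))
        except InputError:
            hr, ci = None, None
        return SubgroupResult(name=name, n=len(sub), km_by_group=km,
                              logrank_p=lr.p_value, hazard_ratio=hr,
                              ci95=ci, estimable=True)

    @staticmethod
    def _group_balance(df: pd.DataFrame) -> pd.DataFrame:
        """Clinicopathological comparability of the low/high groups."""
        rows = []
        if df["score_group"].nunique() < 2:
            return pd.DataFrame(columns=["variable", "test", "p_value"])
        mw = compare_groups(df["age"], df["score_group"],
                            kind="mann_whitney")
        rows.append(("age", "mann_whitney", mw.p_value))
        for var in ("sex", "stage_group", "grade"):
            tab = pd.crosstab(df[var], df["score_group"]).to_numpy()
            if tab.shape[0] < 2:
                rows.append((var, "not_testable", float("nan")))
                continue
            res = compare_groups(tab, kind="chi_square")
            rows.append((var, res.kind, res.p_value))
        return pd.DataFrame(rows, columns=["variable", "test", "p_value"])


@dataclass
class PrognosisResults:
    """Fitted prognostic contrast between low/high score groups."""

    model: PrognosisModel
    cohort: pd.DataFrame
    roc: RocResult
    cutoff: CutoffResult
    km_by_group: dict
    logrank_p: float | None
    cox: CoxResult | None
    subgroups: dict
    group_balance: pd.DataFrame
    warnings: tuple[str, ...] = ()

    # -- accessors ---------------------------------------------------------

    @property
    def score_group_hr(self) -> float | None:
        """Adjusted hazard ratio of high vs low expression."""
        if self.cox is None:
            return None
        key = [i for i in self.cox.table.index if i.startswith("score_group")]
        return float(self.cox.table.loc[key[0], "hazard_ratio"]) \
            if key else None

    def five_year_survival(self, group: str) -> float | None:
        curve = self.km_by_group.get(group)
        return None if curve is None else curve.five_year_survival

    def median_survival(self, group: str) -> float | None:
        curve = self.km_by_group.get(group)
        return None if curve is None else curve.median_months

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Prognostic analysis" + " " * 21 + "=" * 30,
            f"Score: {self.model.score_col}    n = {len(self.cohort)}"
            f"    deaths = {int(self.cohort['event'].sum())}",
            f"ROC AUC (mortality): {self.roc.auc:.3f}",
            f"Cutoff ({self.cutoff.method}): {self.cutoff.cutoff:.3g}  "
            f"[sens {self.cutoff.sensitivity:.3f}, "
            f"spec {self.cutoff.specificity:.3f}]",
            "",
        ]
        for g in ("low", "high"):
            curve = self.km_by_group.get(g)
            if curve is None:
                continue
            med = ("not reached" if curve.median_months is None
                   else f"{curve.median_months:.1f} mo")
            lines.append(
                f"{g:>5} group: n={curve.n}  median survival {med}  "
                f"5-year survival {100 * curve.five_year_survival:.1f}%")
        if self.logrank_p is not None:
            lines.append(f"Log-rank p (low vs high): {self.logrank_p:.4f}")
        if self.cox is not None:
            lines += ["", f"Multivariate Cox ({self.cox.ties} ties, "
                          f"converged={self.cox.converged})",
                      self.cox.table.to_string(
                          float_format=lambda v: f"{v:.3f}")]
        for sg in self.subgroups.values():
            if sg.estimable:
                hr = ("n/a" if sg.hazard_ratio is None
                      else f"{sg.hazard_ratio:.2f} "
                           f"[{sg.ci95[0]:.2f}-{sg.ci95[1]:.2f}]")
                lines.append(f"Stage {sg.name} (n={sg.n}): HR {hr}, "
                             f"log-rank p={sg.logrank_p:.4f}")
            else:
                lines.append(f"Stage {sg.name} (n={sg.n}): not estimable "
                             f"({sg.reason})")
        if self.warnings:
            lines += ["", "Warnings:"] + [f"  - {w}" for w in self.warnings]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable report of the fitted quantities."""
        out = {
            "score": self.model.score_col,
            "n": int(len(self.cohort)),
            "n_events": int(self.cohort["event"].sum()),
            "auc": self.roc.auc,
            "cutoff": {"value": self.cutoff.cutoff,
                       "method": self.cutoff.method,
                       "sensitivity": self.cutoff.sensitivity,
                       "specificity": self.cutoff.specificity},
            "logrank_p": self.logrank_p,
            "groups": {}, "subgroups": {},
            "warnings": list(self.warnings),
        }
        for g, curve in self.km_by_group.items():
            out["groups"][g] = {
                "n": curve.n, "n_events": curve.n_events,
                "median_months": curve.median_months,
                "five_year_survival": curve.five_year_survival,
            }
        if self.cox is not None:
            out["cox"] = {
                "ties": self.cox.ties, "converged": self.cox.converged,
                "table": self.cox.table.round(6).reset_index()
                .rename(columns={"index": "covariate"})
                .to_dict(orient="records"),
            }
        for name, sg in self.subgroups.items():
            out["subgroups"][name] = {
                "n": sg.n, "estimable": sg.estimable,
                "logrank_p": sg.logrank_p, "hazard_ratio": sg.hazard_ratio,
                "ci95": list(sg.ci95) if sg.ci95 else None,
                "reason": sg.reason,
            }
        out["group_balance"] = self.group_balance.to_dict(orient="records")
        return out

    # -- plotting ----------------------------------------------------------

    def plot_km(self, ax=None, subgroup: str | None = None):
        """Kaplan–Meier step curves for the two score groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        curves = (self.subgroups[subgroup].km_by_group if subgroup
                  else self.km_by_group)
        for g, curve in sorted(curves.items()):
            t = np.concatenate([[0.0], curve.event_times])
            s = np.concatenate([[1.0], curve.survival])
            ax.step(t, s, where="post", label=f"{g} (n={curve.n})")
        ax.set_xlabel("Months")
        ax.set_ylabel("Cumulative survival")
        ax.set_ylim(0, 1.05)
        ax.legend()
        title = f"{self.model.score_col} — stage {subgroup}" if subgroup \
            else self.model.score_col
        ax.set_title(title)
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(self.roc.fpr, self.roc.tpr,
                label=f"AUC = {self.roc.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("Sensitivity")
        ax.legend()
        return ax
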