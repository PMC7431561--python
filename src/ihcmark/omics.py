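"""Cross-omics discovery filter and expression fold-change testing.

The discovery step asks which genes behave as Myc-dependent Wnt targets in a
conditional Apc-knockout design: induced after Apc deletion (Apc-null vs
wild-type), with that induction abolished when Myc is co-deleted
(Apc/Myc-null back at wild-type level and well below the Apc-null level),
corroborated on at least three independent probes, and backed by a protein
fold change from the proteomic table. The three transcript criteria per
probe are

* ``fold_APC_WT > 2`` with ``p < 0.05`` (Welch test on log2 values),
* ``0.75 <= ratio_APCMYC_WT <= 1.25`` (a ratio band, no significance
  requirement),
* ``fold_APCMYC_APC < 0.5`` with ``p < 0.05``,

and the protein criterion is ``fold_APC_WT > 1.2``. No multiplicity
adjustment is applied: the filter consumes raw p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, SchemaError
from .simulate import ProbeExpressionTable, ProteinFoldTable


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the Myc-dependent Wnt-target congruence filter."""

    min_fold_apc: float = 2.0
    alpha: float = 0.05
    apcmyc_wt_low: float = 0.75
    apcmyc_wt_high: float = 1.25
    max_fold_apcmyc_apc: float = 0.5
    min_probes: int = 3
    min_protein_fold: float = 1.2

    def __post_init__(self) -> None:
        if not self.apcmyc_wt_low < 1.0 < self.apcmyc_wt_high:
            raise ConfigurationError(
                "APCMYC:WT band must bracket 1 (low < 1 < high)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.min_probes < 1:
            raise ConfigurationError("min_probes must be >= 1")


@dataclass
class CandidateGene:
    gene_id: str
    supporting_probes: tuple[str, ...]
    protein_id: str
    protein_fold: float


@dataclass
class FoldChangeResult:
    """Case/control fold change with a Mann–Whitney p-value."""

    mean_fold: float
    p_value: float
    n_case: int
    n_control: int
    method: str  # "exact" or "normal"


def _welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Two-sided Welch t-test p-value; returns (p, degenerate_flag).

    Probes with zero variance in both groups carry no evidence; they are
    reported as p = 1 with a degenerate flag rather than an error.
    """
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if np.mean(a) == np.mean(b):
            return 1.0, True
        return 1.0, True
    _, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(p):
        return 1.0, True
    return float(p), False


def compute_genotype_ratios(expr: ProbeExpressionTable) -> pd.DataFrame:
    """Per-probe genotype fold changes and Welch p-values.

    Returns a DataFrame indexed by probe with columns ``gene_id,
    fold_APC_WT, p_APC_WT, ratio_APCMYC_WT, fold_APCMYC_APC, p_APCMYC_APC,
    degenerate``. Folds are ``2**(mean log2 difference)``; p-values come
    from two-sided Welch tests on the log2 values for the APC:WT and
    APCMYC:APC contrasts (the APCMYC:WT criterion is a band on the ratio
    only, so no test is attached to it).
    """
    for gt in ("WT", "APC", "APCMYC"):
        cols = expr.samples_of(gt)
        if len(cols) < 2:
            raise SchemaError(
                f"design must contain >= 2 replicates of genotype {gt!r}")

    wt = expr.expression[expr.samples_of("WT")].to_numpy()
    apc = expr.expression[expr.samples_of("APC")].to_numpy()
    apcmyc = expr.expression[expr.samples_of("APCMYC")].to_numpy()

    m_wt, m_apc, m_am = (x.mean(axis=1) for x in (wt, apc, apcmyc))
    rows = []
    for i, probe in enumerate(expr.expression.index):
        p_apc_wt, d1 = _welch_p(apc[i], wt[i])
        p_am_apc, d2 = _welch_p(apcmyc[i], apc[i])
        rows.append({
            "gene_id": expr.probe_to_gene[probe],
            "fold_APC_WT": 2.0 ** (m_apc[i] - m_wt[i]),
            "p_APC_WT": p_apc_wt,
            "ratio_APCMYC_WT": 2.0 ** (m_am[i] - m_wt[i]),
            "fold_APCMYC_APC": 2.0 ** (m_am[i] - m_apc[i]),
            "p_APCMYC_APC": p_am_apc,
            "degenerate": d1 or d2,
        })
    out = pd.DataFrame(rows, index=expr.expression.index)
    out.attrs["test"] = "welch_two_sided_log2"
    return out


def probe_passes(row, criteria: FilterCriteria) -> bool:
    """The per-probe congruence predicate (all three ratio criteria)."""
    return bool(
        row["fold_APC_WT"] > criteria.min_fold_apc
        and row["p_APC_WT"] < criteria.alpha
        and criteria.apcmyc_wt_low <= row["ratio_APCMYC_WT"]
        <= criteria.apcmyc_wt_high
        and row["fold_APCMYC_APC"] < criteria.max_fold_apcmyc_apc
        and row["p_APCMYC_APC"] < criteria.alpha
    )


def apply_congruence_filter(
    ratios: pd.DataFrame,
    proteins: ProteinFoldTable,
    criteria: FilterCriteria = FilterCriteria(),
    mode: str = "per_probe",
) -> list[CandidateGene]:
    """Select genes passing the transcript criteria on enough probes AND
    backed by a protein fold above ``min_protein_fold``.

    ``mode="per_probe"`` (default) requires ``min_probes`` probes to each
    pass all three ratio criteria individually. ``mode="gene_mean"``
    evaluates the criteria on gene-level mean folds (geometric mean across
    probes, Fisher-combined p-values) and requires only that the gene has
    ``min_probes`` probes.
    """
    if mode not in ("per_probe", "gene_mean"):
        raise ConfigurationError(f"unknown filter mode {mode!r}")
    if ratios.empty:
        return []

    prot = proteins.table
    gene_protein: dict[str, tuple[str, float]] = {}
    for _, r in prot.iterrows():
        g = r["gene_id"]
        # keep the strongest protein per gene
        if g not in gene_protein or r["fold_APC_WT"] > gene_protein[g][1]:
            gene_protein[g] = (r["protein_id"], float(r["fold_APC_WT"]))

    candidates: list[CandidateGene] = []
    for gene, sub in ratios.groupby("gene_id", sort=True):
        if mode == "per_probe":
            passing = [p for p, row in sub.iterrows()
                       if probe_passes(row, criteria)]
            if len(passing) < criteria.min_probes:
                continue
        else:
            if len(sub) < criteria.min_probes:
                continue
            gm = {c: float(np.exp(np.log(sub[c]).mean()))
                  for c in ("fold_APC_WT", "ratio_APCMYC_WT",
                            "fold_APCMYC_APC")}
            p1 = stats.combine_pvalues(sub["p_APC_WT"])[1]
            p2 = stats.combine_pvalues(sub["p_APCMYC_APC"])[1]
            row = {**gm, "p_APC_WT": p1, "p_APCMYC_APC": p2}
            if not probe_passes(row, criteria):
                continue
            passing = list(sub.index)
        hit = gene_protein.get(gene)
        if hit is None or hit[1] <= criteria.min_protein_fold:
            continue
        candidates.append(CandidateGene(
            gene_id=gene, supporting_probes=tuple(passing),
            protein_id=hit[0], protein_fold=hit[1]))
    return candidates


# ---------------------------------------------------------------------------
# Case/control fold-change comparison (human qPCR cohorts)
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 12


def _mann_whitney_exact_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided exact Mann–Whitney p by full enumeration of labelings.

    Handles ties correctly (the rank-sum distribution is taken over all
    C(n, n_case) relabelings of the pooled sample). Two-sided p is
    2 * min(P(U <= u), P(U >= u)) capped at 1.
    """
    pooled = np.concatenate([case, control])
    n, n1 = len(pooled), len(case)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array([ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
                   for idx in itertools.combinations(range(n), n1)])
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def fold_change_test(case_values, control_values) -> FoldChangeResult:
    """Mean fold change (case/control, linear scale) with Mann–Whitney p.

    Uses exact enumeration when the pooled sample has at most 12 values,
    and the tie-corrected normal approximation otherwise.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise InputError("both groups must be non-empty")
    if control.mean() == 0.0:
        raise InputError("control mean is 0; fold change undefined")

    if case.size + control.size <= _EXACT_MAX_N:
        p = _mann_whitney_exact_p(case, control)
        method = "exact"
    else:
        p = float(stats.mannwhitneyu(case, control, alternative="two-sided",
                                     method="asymptotic").pvalue)
        method = "normal"
    return FoldChangeResult(
        mean_fold=float(case.mean() / control.mean()), p_value=p,
        n_case=int(case.size), n_control=int(control.size), method=method)
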