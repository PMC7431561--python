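"""Genotype ratio statistics, the congruence filter, and fold-change tests
checked against independent hand-computed and brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ihcmark.errors import InputError, SchemaError
from ihcmark.omics import (FilterCriteria, apply_congruence_filter,
                           compute_genotype_ratios, fold_change_test)
from ihcmark.simulate import (OmicsSimConfig, ProbeExpressionTable,
                              ProteinFoldTable, generate_omics_dataset)


def _make_expr(probe_values: dict, gene_of: dict) -> ProbeExpressionTable:
    """Build a table from {probe: {genotype: [log2 values]}}."""
    samples, design = [], []
    any_probe = next(iter(probe_values.values()))
    for gt, vals in any_probe.items():
        for i in range(len(vals)):
            samples.append(f"{gt}_{i + 1}")
            design.append(gt)
    rows = {p: np.concatenate([np.asarray(v[gt], dtype=float)
                               for gt in any_probe])
            for p, v in probe_values.items()}
    expr = pd.DataFrame(rows, index=samples).T
    expr.index.name = "probe_id"
    return ProbeExpressionTable(
        expression=expr,
        probe_to_gene=pd.Series({p: gene_of[p] for p in probe_values},
                                name="gene_id"),
        design=pd.Series(design, index=samples, name="genotype"))


def welch_p_oracle(a, b):
    """Textbook Welch t-test with Welch–Satterthwaite df."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * tdist.sf(abs(t), df)


class TestGenotypeRatios:
    def test_identical_means_give_fold_one(self):
        expr = _make_expr(
            {"p1": {"WT": [5, 5.2, 4.8, 5.0], "APC": [5.1, 4.9, 5.2, 4.8],
                    "APCMYC": [5, 5, 5.1, 4.9]}}, {"p1": "G1"})
        r = compute_genotype_ratios(expr)
        assert r.loc["p1", "fold_APC_WT"] == pytest.approx(1.0)

    def test_two_log2_units_is_fourfold(self):
        expr = _make_expr(
            {"p1": {"WT": [5, 5.5, 4.5, 5.0], "APC": [7, 7.5, 6.5, 7.0],
                    "APCMYC": [5, 5.5, 4.5, 5.0]}}, {"p1": "G1"})
        r = compute_genotype_ratios(expr)
        assert r.loc["p1", "fold_APC_WT"] == pytest.approx(4.0)
        assert r.loc["p1", "fold_APCMYC_APC"] == pytest.approx(0.25)

    def test_welch_p_matches_hand_formula(self):
        wt = [5.1, 4.7, 5.3, 5.0]
        apc = [6.4, 6.9, 6.1, 6.6]
        am = [5.2, 4.9, 5.1, 5.4]
        expr = _make_expr({"p1": {"WT": wt, "APC": apc, "APCMYC": am}},
                          {"p1": "G1"})
        r = compute_genotype_ratios(expr)
        assert r.loc["p1", "p_APC_WT"] == pytest.approx(
            welch_p_oracle(apc, wt), abs=1e-10)
        assert r.loc["p1", "p_APCMYC_APC"] == pytest.approx(
            welch_p_oracle(am, apc), abs=1e-10)

    def test_zero_variance_probe_flagged_not_fatal(self):
        expr = _make_expr(
            {"p1": {"WT": [5, 5, 5, 5], "APC": [5, 5, 5, 5],
                    "APCMYC": [5, 5, 5, 5]}}, {"p1": "G1"})
        r = compute_genotype_ratios(expr)
        assert r.loc["p1", "degenerate"]
        assert r.loc["p1", "p_APC_WT"] == 1.0

    def test_missing_genotype_is_design_error(self):
        expr = _make_expr(
            {"p1": {"WT": [5, 5.1], "APC": [6, 6.1]}}, {"p1": "G1"})
        with pytest.raises(SchemaError, match="APCMYC"):
            compute_genotype_ratios(expr)

    def test_scale_invariance_of_folds_and_pvalues(self, omics_default):
        expr, _, _ = omics_default
        shifted = ProbeExpressionTable(
            expression=expr.expression + np.log2(7.3),  # x7.3 linear scale
            probe_to_gene=expr.probe_to_gene, design=expr.design)
        a = compute_genotype_ratios(expr)
        b = compute_genotype_ratios(shifted)
        for col in ("fold_APC_WT", "p_APC_WT", "ratio_APCMYC_WT",
                    "fold_APCMYC_APC", "p_APCMYC_APC"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-9)


def _random_ratio_table(rng, n_genes=200, probes_per_gene=3):
    rows = []
    for g in range(n_genes):
        for p in range(probes_per_gene):
            rows.append({
                "gene_id": f"G{g:04d}",
                "fold_APC_WT": float(rng.lognormal(0.5, 0.8)),
                "p_APC_WT": float(rng.random()),
                "ratio_APCMYC_WT": float(rng.lognormal(0.0, 0.3)),
                "fold_APCMYC_APC": float(rng.lognormal(-0.7, 0.6)),
                "p_APCMYC_APC": float(rng.random()),
                "degenerate": False,
            })
    idx = [f"G{g:04d}_p{p}" for g in range(n_genes)
           for p in range(probes_per_gene)]
    return pd.DataFrame(rows, index=idx)


def _random_proteins(rng, n_genes=200):
    gene_ids = [f"G{g:04d}" for g in range(n_genes) if rng.random() < 0.7]
    return ProteinFoldTable(pd.DataFrame({
        "protein_id": [f"P_{g}" for g in gene_ids],
        "gene_id": gene_ids,
        "fold_APC_WT": rng.lognormal(0.2, 0.4, size=len(gene_ids)),
    }))


def brute_force_candidates(ratios, proteins, criteria):
    """Gene-by-gene re-evaluation of the filter predicate in plain Python."""
    out = []
    best_fold = {}
    for _, r in proteins.table.iterrows():
        g = r["gene_id"]
        if g not in best_fold or r["fold_APC_WT"] > best_fold[g]:
            best_fold[g] = r["fold_APC_WT"]
    for gene in sorted(set(ratios["gene_id"])):
        sub = ratios[ratios["gene_id"] == gene]
        n_pass = 0
        for _, row in sub.iterrows():
            ok = (row["fold_APC_WT"] > criteria.min_fold_apc
                  and row["p_APC_WT"] < criteria.alpha
                  and criteria.apcmyc_wt_low <= row["ratio_APCMYC_WT"]
                  <= criteria.apcmyc_wt_high
                  and row["fold_APCMYC_APC"] < criteria.max_fold_apcmyc_apc
                  and row["p_APCMYC_APC"] < criteria.alpha)
            n_pass += ok
        if (n_pass >= criteria.min_probes and gene in best_fold
                and best_fold[gene] > criteria.min_protein_fold):
            out.append(gene)
    return out


class TestCongruenceFilter:
    CRITERIA = FilterCriteria()

    @staticmethod
    def _single_gene_table(ratio_apcmyc_wt_probe3=1.05):
        rows = []
        for i, band in enumerate([1.05, 1.05, ratio_apcmyc_wt_probe3]):
            rows.append({"gene_id": "G1", "fold_APC_WT": 2.5,
                         "p_APC_WT": 0.01, "ratio_APCMYC_WT": band,
                         "fold_APCMYC_APC": 0.4, "p_APCMYC_APC": 0.01,
                         "degenerate": False})
        return pd.DataFrame(rows, index=[f"G1_p{i}" for i in range(3)])

    @staticmethod
    def _protein(fold=1.3):
        return ProteinFoldTable(pd.DataFrame(
            {"protein_id": ["P_G1"], "gene_id": ["G1"],
             "fold_APC_WT": [fold]}))

    def test_gene_inside_all_thresholds_retained(self):
        cands = apply_congruence_filter(self._single_gene_table(),
                                        self._protein(), self.CRITERIA)
        assert [c.gene_id for c in cands] == ["G1"]
        assert len(cands[0].supporting_probes) == 3

    def test_band_violation_on_one_of_three_probes_rejects(self):
        ratios = self._single_gene_table(ratio_apcmyc_wt_probe3=1.3)
        assert apply_congruence_filter(ratios, self._protein(),
                                       self.CRITERIA) == []

    def test_protein_fold_at_threshold_rejects(self):
        assert apply_congruence_filter(self._single_gene_table(),
                                       self._protein(fold=1.2),
                                       self.CRITERIA) == []

    def test_empty_inputs_yield_empty_candidates(self):
        empty = pd.DataFrame(columns=["gene_id", "fold_APC_WT", "p_APC_WT",
                                      "ratio_APCMYC_WT", "fold_APCMYC_APC",
                                      "p_APCMYC_APC"])
        assert apply_congruence_filter(empty, self._protein(),
                                       self.CRITERIA) == []

    def test_matches_brute_force_on_random_tables(self, rng):
        ratios = _random_ratio_table(rng)
        proteins = _random_proteins(rng)
        got = [c.gene_id for c in
               apply_congruence_filter(ratios, proteins, self.CRITERIA)]
        assert got == brute_force_candidates(ratios, proteins,
                                             self.CRITERIA)

    @pytest.mark.parametrize("relaxed", [
        dict(min_fold_apc=1.5), dict(apcmyc_wt_low=0.6),
        dict(apcmyc_wt_high=1.5), dict(max_fold_apcmyc_apc=0.8),
        dict(min_probes=2), dict(min_protein_fold=1.0),
        dict(alpha=0.2),
    ])
    def test_monotone_under_criterion_relaxation(self, rng, relaxed):
        ratios = _random_ratio_table(rng, n_genes=120)
        proteins = _random_proteins(rng, n_genes=120)
        strict = {c.gene_id for c in
                  apply_congruence_filter(ratios, proteins, self.CRITERIA)}
        loose = {c.gene_id for c in apply_congruence_filter(
            ratios, proteins, FilterCriteria(**relaxed))}
        assert strict <= loose

    def test_planted_truth_recovered_end_to_end(self):
        cfg = OmicsSimConfig(effect_fold_apc=4.0, noise_sd=0.1)
        expr, proteins, truth = generate_omics_dataset(cfg, seed=7)
        ratios = compute_genotype_ratios(expr)
        got = {c.gene_id for c in apply_congruence_filter(ratios, proteins)}
        assert got == set(truth.planted_gene_ids)

    def test_gene_mean_mode_accepts_probe_level_jitter(self):
        # one probe narrowly misses the band; gene means still pass
        ratios = self._single_gene_table(ratio_apcmyc_wt_probe3=1.27)
        assert apply_congruence_filter(ratios, self._protein(),
                                       self.CRITERIA) == []
        cands = apply_congruence_filter(ratios, self._protein(),
                                        self.CRITERIA, mode="gene_mean")
        assert [c.gene_id for c in cands] == ["G1"]


def mw_exact_oracle(case, control):
    """Exact two-sided Mann–Whitney p by counting pairwise wins over all
    relabelings (independent of the rank-sum route)."""
    pooled = list(case) + list(control)
    n1 = len(case)

    def u_stat(idx):
        group = set(idx)
        cs = [pooled[i] for i in idx]
        ct = [pooled[i] for i in range(len(pooled)) if i not in group]
        return sum((a > b) + 0.5 * (a == b) for a in cs for b in ct)

    u_obs = u_stat(range(n1))
    us = [u_stat(idx)
          for idx in itertools.combinations(range(len(pooled)), n1)]
    p_le = sum(u <= u_obs + 1e-12 for u in us) / len(us)
    p_ge = sum(u >= u_obs - 1e-12 for u in us) / len(us)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestFoldChangeTest:
    def test_identical_groups_fold_one_p_one(self):
        r = fold_change_test([1, 2, 3], [1, 2, 3])
        assert r.mean_fold == 1.0
        assert r.p_value == 1.0
        assert r.method == "exact"

    def test_doubled_values_fold_two_with_exact_p(self):
        control = [1.0, 1.5, 2.0, 2.5, 3.0]
        case = [2 * v for v in control]
        r = fold_change_test(case, control)
        assert r.mean_fold == pytest.approx(2.0)
        assert r.p_value == pytest.approx(mw_exact_oracle(case, control),
                                          abs=1e-12)

    def test_complete_separation_3v3_exact_p(self):
        r = fold_change_test([4, 5, 6], [1, 2, 3])
        assert r.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_exact_branch_matches_enumeration_with_ties(self, rng):
        for _ in range(5):
            case = rng.integers(1, 5, size=4).astype(float)
            control = rng.integers(1, 5, size=5).astype(float)
            r = fold_change_test(case, control)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(
                mw_exact_oracle(case, control), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        case = rng.normal(2, 0.5, size=20)
        control = rng.normal(1, 0.5, size=20)
        r = fold_change_test(case, control)
        assert r.method == "normal"
        assert 0 <= r.p_value <= 1

    def test_empty_group_and_zero_control_mean_rejected(self):
        with pytest.raises(InputError):
            fold_change_test([], [1, 2])
        with pytest.raises(InputError):
            fold_change_test([1, 2], [0, 0])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=6),
       st.lists(st.floats(0.1, 10.0), min_size=2, max_size=6))
def test_fold_change_p_always_valid(case, control):
    r = fold_change_test(case, control)
    assert 0.0 <= r.p_value <= 1.0
    assert r.mean_fold > 0
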