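"""End-to-end orchestration of the discovery and prognosis flows.

Both entry points consume a flat config dict (loadable from YAML/JSON via
:func:`ihcmark.io.load_config`), write their reports plus a run manifest
into ``out_dir``, and return the manifest. All randomness flows from the
single ``seed`` entry; stage seeds are derived deterministically from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .ihc import IntensityZones, score_sample, DEFAULT_POSITIVITY_OD
from .io import (read_cohort_csv, read_image, read_probe_table,
                 read_protein_table, write_cohort_csv)
from .omics import FilterCriteria, apply_congruence_filter, \
    compute_genotype_ratios
from .prognosis import PrognosisModel


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


class RunManifest:
    """Reproducibility record for one pipeline run."""

    def __init__(self, flow: str, config: dict, seed: int | None):
        self.data = {
            "flow": flow,
            "version": __version__,
            "seed": seed,
            "config": config,
            "inputs": {},
            "outputs": {},
            "timings_s": {},
            "warnings": [],
        }

    def add_input(self, name: str, path):
        self.data["inputs"][name] = {"path": str(path),
                                     "sha256": _sha256(path)}

    def add_output(self, name: str, path):
        self.data["outputs"][name] = {"path": str(path),
                                      "sha256": _sha256(path)}

    def warn(self, message: str):
        if message not in self.data["warnings"]:
            self.data["warnings"].append(message)

    def write(self, path):
        Path(path).write_text(json.dumps(self.data, indent=1,
                                         default=str))


def _timed(manifest: RunManifest, stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            manifest.data["timings_s"][stage] = round(
                time.perf_counter() - self.t0, 4)
            return False
    return _Timer()


# ---------------------------------------------------------------------------
# Discovery flow: expression + protein tables -> candidate genes
# ---------------------------------------------------------------------------

def run_discovery(config: dict) -> RunManifest:
    """Compute genotype ratios, apply the congruence filter, write reports.

    Config keys: ``expression_tsv, design_tsv, protein_tsv, out_dir``;
    optional ``criteria`` (FilterCriteria field overrides), ``mode``
    (``per_probe``/``gene_mean``), ``seed``.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("discovery", config, config.get("seed"))

    for key in ("expression_tsv", "design_tsv", "protein_tsv"):
        path = Path(config[key])
        if not path.exists():
            raise SchemaError(f"input file not found: {path}")
        manifest.add_input(key, path)

    with _timed(manifest, "read"):
        expr = read_probe_table(config["expression_tsv"],
                                config["design_tsv"])
        proteins = read_protein_table(config["protein_tsv"])

    criteria = FilterCriteria(**config.get("criteria", {}))
    with _timed(manifest, "ratios"):
        ratios = compute_genotype_ratios(expr)
    n_degenerate = int(ratios["degenerate"].sum())
    if n_degenerate:
        manifest.warn(f"{n_degenerate} probes had degenerate variance; "
                      f"p reported as 1")
    known_genes = set(expr.probe_to_gene)
    n_unmapped = int((~proteins.table["gene_id"].isin(known_genes)).sum())
    if n_unmapped:
        manifest.warn(f"{n_unmapped} proteins map to no expressed gene; "
                      f"ignored")

    with _timed(manifest, "filter"):
        candidates = apply_congruence_filter(
            ratios, proteins, criteria, mode=config.get("mode", "per_probe"))

    ratio_path = out_dir / "ratio_table.tsv"
    ratios.round(10).to_csv(ratio_path, sep="\t")
    cand_rows = [{
        "gene_id": c.gene_id,
        "n_supporting_probes": len(c.supporting_probes),
        "supporting_probes": ";".join(c.supporting_probes),
        "protein_id": c.protein_id,
        "protein_fold": round(c.protein_fold, 6),
    } for c in candidates]
    cand_tsv = out_dir / "candidates.tsv"
    pd.DataFrame(cand_rows, columns=["gene_id", "n_supporting_probes",
                                     "supporting_probes", "protein_id",
                                     "protein_fold"]
                 ).to_csv(cand_tsv, sep="\t", index=False)
    cand_json = out_dir / "candidates.json"
    cand_json.write_text(json.dumps({
        "n_candidates": len(candidates),
        "criteria": dataclasses.asdict(criteria),
        "mode": config.get("mode", "per_probe"),
        "candidates": cand_rows,
    }, indent=1))

    for name, path in (("ratio_table", ratio_path),
                       ("candidates_tsv", cand_tsv),
                       ("candidates_json", cand_json)):
        manifest.add_output(name, path)
    manifest.write(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Prognosis flow: cohort (+ optional images) -> survival report
# ---------------------------------------------------------------------------

def _score_from_images(cohort: pd.DataFrame, config: dict,
                       manifest: RunManifest) -> pd.DataFrame:
    """Fill the score column by scoring each patient's field images."""
    score_col = config.get("score", "nuclear_pct")
    compartment = ("nuclear" if "nuclear" in score_col else "cytoplasmic")
    image_dir = Path(config.get("image_dir", "."))
    strict = bool(config.get("strict", False))
    zones = IntensityZones(*config.get("zones", (60, 120, 180)))
    pos_od = float(config.get("positivity_od", DEFAULT_POSITIVITY_OD))

    cohort = cohort.copy()
    scores = []
    for _, row in cohort.iterrows():
        paths = [image_dir / p for p in str(row["fields"]).split(";")]
        imgs = [read_image(p) for p in paths]
        res = score_sample(imgs, compartment, zones=zones,
                           positivity_od_threshold=pos_od, strict=strict)
        for w in res.warnings:
            manifest.warn(f"patient {row.get('id', '?')}: {w}")
        scores.append(res.score)
    cohort[score_col] = scores
    return cohort


def run_prognosis(config: dict) -> RunManifest:
    """Score (if needed), dichotomize and model a cohort; write reports.

    Config keys: ``cohort_csv, out_dir``; optional ``score`` (column,
    default ``nuclear_pct``), ``cutoff`` (fixed) or ``cutoff_method``,
    ``image_dir`` (with a ``fields`` cohort column for raster scoring),
    ``strict``, ``zones``, ``positivity_od``, ``seed``, ``plots``.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("prognosis", config, config.get("seed"))

    cohort_path = Path(config["cohort_csv"])
    if not cohort_path.exists():
        raise SchemaError(f"input file not found: {cohort_path}")
    manifest.add_input("cohort_csv", cohort_path)

    with _timed(manifest, "read"):
        cohort = read_cohort_csv(cohort_path)
    score_col = config.get("score", "nuclear_pct")
    if score_col not in cohort.columns and "fields" in cohort.columns:
        with _timed(manifest, "image_scoring"):
            cohort = _score_from_images(cohort, config, manifest)
        write_cohort_csv(cohort, out_dir / "scored_cohort.csv")
        manifest.add_output("scored_cohort", out_dir / "scored_cohort.csv")

    with _timed(manifest, "model"):
        model = PrognosisModel(
            cohort, score_col=score_col,
            cutoff=config.get("cutoff"),
            cutoff_method=config.get("cutoff_method", "balanced"))
        results = model.fit()
    for w in results.warnings:
        manifest.warn(w)

    report_json = out_dir / "prognosis.json"
    report_json.write_text(json.dumps(results.to_dict(), indent=1,
                                      default=_jsonable))
    report_md = out_dir / "prognosis.md"
    report_md.write_text("```\n" + results.summary() + "\n```\n")
    manifest.add_output("report_json", report_json)
    manifest.add_output("report_md", report_md)

    if config.get("plots", True):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        with _timed(manifest, "plots"):
            ax = results.plot_km()
            km_path = out_dir / "km_overall.svg"
            ax.figure.savefig(km_path)
            plt.close(ax.figure)
            manifest.add_output("km_overall", km_path)
            for name, sg in results.subgroups.items():
                if not sg.km_by_group:
                    continue
                ax = results.plot_km(subgroup=name)
                p = out_dir / f"km_stage_{name}.svg"
                ax.figure.savefig(p)
                plt.close(ax.figure)
                manifest.add_output(f"km_stage_{name}", p)
            ax = results.plot_roc()
            roc_path = out_dir / "roc.svg"
            ax.figure.savefig(roc_path)
            plt.close(ax.figure)
            manifest.add_output("roc", roc_path)

    manifest.write(out_dir / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
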