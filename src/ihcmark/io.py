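"""Readers and writers for the pipeline's plain-text and raster formats.

Tables travel as headered TSV/CSV; images as 8-bit RGB PNG; truth labels as
JSON plus a 16-bit label raster PNG; configs as YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import SchemaError
from .simulate import (GENOTYPES, ImageTruth, ProbeExpressionTable,
                       ProteinFoldTable)


# -- expression tables -----------------------------------------------------

def write_probe_table(expr: ProbeExpressionTable, values_path, design_path):
    """TSV pair: probe_id + gene_id + one column per sample; and the
    two-column sample,genotype design."""
    tbl = expr.expression.copy()
    tbl.insert(0, "gene_id", expr.probe_to_gene)
    tbl.to_csv(values_path, sep="\t")
    expr.design.rename_axis("sample").to_frame().to_csv(
        design_path, sep="\t")


def read_probe_table(values_path, design_path) -> ProbeExpressionTable:
    try:
        tbl = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    except ValueError as exc:
        raise SchemaError(
            f"{values_path}: expected a 'probe_id' column ({exc})") from exc
    if "gene_id" not in tbl.columns:
        raise SchemaError(f"{values_path}: missing 'gene_id' column")
    design_df = pd.read_csv(design_path, sep="\t")
    if not {"sample", "genotype"} <= set(design_df.columns):
        raise SchemaError(
            f"{design_path}: needs 'sample' and 'genotype' columns")
    unknown = set(design_df["genotype"]) - set(GENOTYPES)
    if unknown:
        raise SchemaError(
            f"{design_path}: unknown genotypes {sorted(unknown)}; "
            f"expected a subset of {GENOTYPES}")
    design = design_df.set_index("sample")["genotype"]
    gene = tbl.pop("gene_id")
    return ProbeExpressionTable(expression=tbl.astype(float),
                                probe_to_gene=gene, design=design)


def write_protein_table(proteins: ProteinFoldTable, path):
    proteins.table.to_csv(path, sep="\t", index=False)


def read_protein_table(path) -> ProteinFoldTable:
    tbl = pd.read_csv(path, sep="\t")
    required = {"protein_id", "gene_id", "fold_APC_WT"}
    if not required <= set(tbl.columns):
        raise SchemaError(f"{path}: protein table needs columns "
                          f"{sorted(required)}, got {list(tbl.columns)}")
    return ProteinFoldTable(tbl)


# -- cohort ----------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path):
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- images ----------------------------------------------------------------

def write_image_png(img: np.ndarray, path):
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB raster (PNG/TIFF); alpha is dropped."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return arr


def read_mask(path) -> np.ndarray:
    """Load a mask raster: any nonzero pixel counts as tissue."""
    with Image.open(path) as im:
        return np.asarray(im.convert("I")) > 0


def write_image_truth(truth: ImageTruth, json_path, labels_path):
    Image.fromarray(truth.nucleus_labels.astype(np.uint16),
                    mode="I;16").save(labels_path)
    payload = {
        "n_nuclei": truth.n_nuclei,
        "n_positive": truth.n_positive,
        "positive_nucleus_ids": sorted(truth.positive_nucleus_ids),
        "cytoplasm_class_fractions":
            truth.cytoplasm_class_fractions().tolist(),
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))


# -- configs ---------------------------------------------------------------

def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
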