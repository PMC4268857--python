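"""Readers and writers for the pipeline's plain-text and image formats.

Expression matrices travel as TSV (genes in rows, header = sample ids),
gene sets as GMT, clinical tables as CSV, per-image stromal fractions as
TSV, and images/masks as 8-bit PNG. Writers and readers round-trip
losslessly (images up to 8-bit quantisation), and readers validate schema
with row/column context in error messages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .signature import GeneSet

__all__ = [
    "read_expression", "write_expression",
    "read_gmt", "write_gmt",
    "read_clinical", "write_clinical",
    "read_fractions", "write_fractions",
    "read_image", "write_image", "write_mask", "write_overlay",
    "write_json", "read_json",
]

CLINICAL_REQUIRED = ("entry_time", "exit_time", "event")


def read_expression(path, impute: str | None = None) -> pd.DataFrame:
    """Read a genes x samples log2 TSV; gene ids must be unique.

    Missing values raise by default; ``impute='gene_mean'`` fills them with
    the gene's row mean.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes[:5]}")
    if expr.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if expr.isna().any().any():
        if impute == "gene_mean":
            expr = expr.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            bad = expr.index[expr.isna().any(axis=1)].tolist()
            raise ValueError(f"{path}: missing values in genes {bad[:5]}")
    return expr.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_gmt(path) -> dict[str, GeneSet]:
    """Read gene sets from GMT (name, description, then member ids per line)."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one gene (got {len(fields)} fields)")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, tuple(genes))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "synthetic"] + list(gs.genes)) + "\n")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical CSV indexed by sample_id; validates the time schema."""
    table = pd.read_csv(path, index_col=0)
    missing = [c for c in CLINICAL_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns {missing}")
    bad = table.index[table["exit_time"] < table["entry_time"]].tolist()
    if bad:
        raise ValueError(f"{path}: exit before entry for samples {bad[:5]}")
    if not table["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event column must be 0/1")
    return table


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="sample_id")


def read_fractions(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "stromal_fraction" not in table.columns:
        raise ValueError(f"{path}: missing stromal_fraction column")
    frac = table["stromal_fraction"].dropna()
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError(f"{path}: stromal fractions outside [0, 1]")
    return table


def write_fractions(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="image_id", float_format="%.6g")


def read_image(path) -> np.ndarray:
    img = np.asarray(Image.open(path).convert("RGB"))
    return img


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def write_mask(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8),
                    mode="L").save(path)


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_overlay(image: np.ndarray, stroma_mask: np.ndarray, path,
                  alpha: float = 0.45) -> None:
    """Image with the stroma mask tinted green, for visual QC."""
    img = np.asarray(image, dtype=float).copy()
    green = np.array([0.0, 200.0, 0.0])
    m = np.asarray(stroma_mask, dtype=bool)
    img[m] = (1 - alpha) * img[m] + alpha * green
    write_image(np.clip(np.round(img), 0, 255).astype(np.uint8), path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
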