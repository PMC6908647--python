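"""Readers and writers for the pipeline's tabular formats.

All tables are TSV with a header row.  The in-memory containers are plain
pandas objects:

* beta matrix      -- DataFrame, probes x samples, floats in [0, 1], NaN = missing
* probe annotation -- DataFrame indexed by probe_id with columns
                      ``chromosome, position, gene, gene_region, cgi_relation, snp_flag``;
                      multi-gene probes use semicolon-joined parallel lists in
                      ``gene`` and ``gene_region`` (450K manifest convention)
* count matrix     -- DataFrame, genes x samples, non-negative integers
* sample sheet     -- DataFrame indexed by sample_id with a mandatory
                      ``condition`` column (tumor/normal), a ``cancer_type``
                      column and optional clinical categoricals

Coordinates are 1-based inclusive, matching array manifests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
CGI_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
CONDITIONS = ("tumor", "normal")
#: manifest region classes treated as promoter (TSS1500 = 200-1500 bp upstream
#: of the TSS, TSS200 = within 200 bp)
PROMOTER_REGIONS = ("TSS1500", "TSS200")

MANIFEST_COLUMNS = ["probe_id", "chromosome", "position", "gene",
                    "gene_region", "cgi_relation", "snp_flag"]
SAMPLE_SHEET_COLUMNS = ["sample_id", "condition"]


class FormatError(ValueError):
    """A pipeline input file violates its documented dialect."""


def _check_unique(ids, what: str) -> None:
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {what} id(s): {sorted(set(dup))[:5]}")


# ---------------------------------------------------------------------------
# beta matrix

def validate_beta_matrix(beta: pd.DataFrame) -> None:
    """Raise :class:`FormatError` unless *beta* is a valid beta matrix."""
    _check_unique(beta.index, "probe")
    _check_unique(beta.columns, "sample")
    values = beta.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"beta value {values[i, j]!r} out of [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )


def read_beta_matrix(path) -> pd.DataFrame:
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta = beta.astype(float)
    validate_beta_matrix(beta)
    return beta


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    validate_beta_matrix(beta)
    beta.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


# ---------------------------------------------------------------------------
# probe annotation

def validate_annotation(ann: pd.DataFrame) -> None:
    _check_unique(ann.index, "probe")
    missing = [c for c in MANIFEST_COLUMNS[1:] if c not in ann.columns]
    if missing:
        raise FormatError(
            f"manifest missing column(s) {missing}; expected header "
            f"{MANIFEST_COLUMNS}"
        )
    if (ann["position"] < 1).any():
        bad = ann.index[ann["position"] < 1][0]
        raise FormatError(f"probe {bad!r}: position must be >= 1 (1-based)")
    for probe, gene, region in iter_gene_links(ann):
        if region not in GENE_REGIONS:
            raise FormatError(
                f"probe {probe!r}: gene_region {region!r} not in {GENE_REGIONS}"
            )
    bad_rel = ~ann["cgi_relation"].isin(CGI_RELATIONS)
    if bad_rel.any():
        probe = ann.index[bad_rel][0]
        raise FormatError(
            f"probe {probe!r}: cgi_relation {ann.loc[probe, 'cgi_relation']!r} "
            f"not in {CGI_RELATIONS}"
        )


def iter_gene_links(ann: pd.DataFrame) -> Iterator[tuple[str, str, str]]:
    """Yield ``(probe_id, gene, gene_region)`` for every probe-gene link.

    Multi-gene probes store semicolon-joined parallel lists; probes with an
    empty ``gene`` field yield nothing.
    """
    for probe, gene_field, region_field in zip(
        ann.index, ann["gene"].fillna(""), ann["gene_region"].fillna("")
    ):
        if not gene_field:
            continue
        genes = str(gene_field).split(";")
        regions = str(region_field).split(";")
        if len(genes) != len(regions):
            raise FormatError(
                f"probe {probe!r}: gene and gene_region lists differ in length"
            )
        for gene, region in zip(genes, regions):
            yield probe, gene, region


def read_manifest(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene": "string", "gene_region": "string"})
    if "probe_id" not in ann.columns:
        raise FormatError(f"manifest missing probe_id; expected header {MANIFEST_COLUMNS}")
    ann = ann.set_index("probe_id")
    missing = [c for c in MANIFEST_COLUMNS[1:] if c not in ann.columns]
    if missing:
        raise FormatError(
            f"manifest missing column(s) {missing}; expected header "
            f"{MANIFEST_COLUMNS}"
        )
    ann["snp_flag"] = ann["snp_flag"].astype(bool)
    validate_annotation(ann)
    return ann


def write_manifest(ann: pd.DataFrame, path) -> None:
    validate_annotation(ann)
    ann.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# count matrix

def validate_counts(counts: pd.DataFrame) -> None:
    _check_unique(counts.index, "gene")
    _check_unique(counts.columns, "sample")
    values = counts.to_numpy()
    if np.any(values != np.floor(values)) or np.any(np.isnan(values)):
        i, j = np.argwhere((values != np.floor(values)) | np.isnan(values))[0]
        raise FormatError(
            f"count {values[i, j]!r} not a non-negative integer at gene "
            f"{counts.index[i]!r}, sample {counts.columns[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count at gene {counts.index[i]!r}, sample {counts.columns[j]!r}"
        )


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(counts)
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    validate_counts(counts)
    counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample sheet

def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    _check_unique(sheet.index, "sample")
    if "condition" not in sheet.columns:
        raise FormatError(
            f"sample sheet missing mandatory column 'condition'; expected at "
            f"least {SAMPLE_SHEET_COLUMNS}"
        )
    bad = ~sheet["condition"].isin(CONDITIONS)
    if bad.any():
        sample = sheet.index[bad][0]
        raise FormatError(
            f"sample {sample!r}: condition {sheet.loc[sample, 'condition']!r} "
            f"not in {CONDITIONS}"
        )


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns:
        raise FormatError("sample sheet missing mandatory column 'sample_id'")
    sheet = sheet.set_index("sample_id")
    validate_sample_sheet(sheet)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT) and JSON helpers

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
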