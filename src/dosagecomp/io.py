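"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain tab-delimited text; gene sets use GMT.
Writers format floats with ``%.10g`` so that a write/read round trip is
bit-exact and repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datamodel import (
    DataModelError,
    GeneSetCollection,
    OmicsMatrix,
    validate_arms,
    validate_gene_annotation,
    validate_sample_annotation,
    validate_segments,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def read_omics_matrix(
    path, layer: str, scale: str, missing_token: str = "NA"
) -> OmicsMatrix:
    """Read a tab-delimited gene x sample matrix.

    First column holds gene IDs, header row holds sample IDs; cells equal to
    ``missing_token`` become missing values, any other non-numeric cell is an
    error.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
        dtype=str,
    )
    if df.index.name is None or df.columns.size == 0:
        raise DataModelError(f"malformed matrix header in {path}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise DataModelError(f"non-numeric cell in {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataModelError(f"duplicate gene row(s) in {path}: {dup[:5]}")
    return OmicsMatrix(layer=layer, scale=scale, values=df)


def write_omics_matrix(matrix: OmicsMatrix, path, missing_token: str = "NA") -> None:
    matrix.values.to_csv(
        path, sep="\t", na_rep=missing_token, float_format=FLOAT_FMT
    )


def read_segments(path) -> pd.DataFrame:
    """Read a SEG-like tab-delimited segment file.

    Required columns: sample, chrom, start, end, log2_ratio; coordinates are
    0-based half-open.  A header-only file yields an empty table.
    """
    seg = pd.read_csv(path, sep="\t")
    if seg.empty:
        seg = seg.reindex(columns=["sample", "chrom", "start", "end", "log2_ratio"])
        return validate_segments(seg.astype({"start": "int64", "end": "int64"}, errors="ignore"))
    return validate_segments(seg)


def write_segments(segments: pd.DataFrame, path) -> None:
    validate_segments(segments).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_arm_table(path) -> pd.DataFrame:
    return validate_arms(pd.read_csv(path, sep="\t"))


def write_arm_table(arms: pd.DataFrame, path) -> None:
    validate_arms(arms).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    return validate_gene_annotation(pd.read_csv(path, sep="\t"))


def write_gene_annotation(ann: pd.DataFrame, path) -> None:
    validate_gene_annotation(ann).to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_sample_annotation(path) -> pd.DataFrame:
    return validate_sample_annotation(pd.read_csv(path, sep="\t"))


def write_sample_annotation(ann: pd.DataFrame, path) -> None:
    validate_sample_annotation(ann).to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_gene_sets(path, min_size: int = 5, max_size: int = 500) -> GeneSetCollection:
    """Read a GMT file, dropping sets outside ``[min_size, max_size]``.

    Each GMT line is ``name<TAB>description<TAB>member1<TAB>member2...``.
    The size filter is applied after member de-duplication; the number of
    dropped sets is logged.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataModelError(f"malformed GMT line: {line[:60]!r}")
            name, desc, *members = parts
            if name in descriptions:
                raise DataModelError(f"duplicate gene set name {name!r}")
            members = [m for m in dict.fromkeys(members) if m]
            descriptions[name] = desc
            if not (min_size <= len(members) <= max_size):
                n_dropped += 1
                continue
            sets[name] = members
    if n_dropped:
        logger.info("read_gene_sets: dropped %d set(s) outside [%d, %d]", n_dropped, min_size, max_size)
    return GeneSetCollection(sets, {n: descriptions[n] for n in sets})


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ensure_out_dir(out_dir) -> Path:
    if not str(out_dir):
        raise DataModelError("empty output directory path")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out
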