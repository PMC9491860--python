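"""Neutral-group references, per-layer log2 fold changes, SCNA groups.

For each gene within each tumor type, samples whose DNA log2 copy-number
ratio lies within the neutral band (default ±0.2) form the *neutral group*;
the per-layer medians over that group define the reference against which
every sample's log2 fold change (l2fc) is computed.  The DNA l2fc then bins
each gene/sample observation into one of five SCNA groups:

    deep_loss  x < -0.65
    loss       -0.65 <= x < -0.2
    neutral    -0.2 <= x <= 0.2
    gain       0.2 < x <= 0.65
    high_gain  x > 0.65

The neutral bin is closed on both sides, matching the neutral-group
definition; the outer boundaries resolve their ties inward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataModelError, OmicsMatrix, ProteogenomicDataset

SCNA_GROUPS = ("deep_loss", "loss", "neutral", "gain", "high_gain")


@dataclass
class FoldChangeParams:
    neutral_low: float = -0.2
    neutral_high: float = 0.2
    deep_threshold: float = 0.65
    min_neutral: int = 5
    expression_quantile: float = 0.10
    expression_summary: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        if self.neutral_low >= self.neutral_high:
            raise DataModelError("neutral_low must be < neutral_high")
        if not 0 <= self.expression_quantile < 1:
            raise DataModelError("expression quantile must lie in [0, 1)")
        if self.expression_summary not in ("median", "mean"):
            raise DataModelError("expression_summary must be 'median' or 'mean'")


def assign_scna_group(dna_l2fc) -> np.ndarray | str:
    """Map DNA log2FC to its SCNA group label.

    Accepts a scalar or array; scalars must be finite, array entries that
    are NaN map to the empty label "".
    """
    x = np.asarray(dna_l2fc, dtype=float)
    scalar = x.ndim == 0
    if scalar and not np.isfinite(x):
        raise DataModelError("non-finite DNA log2FC")
    x = np.atleast_1d(x)
    out = np.full(x.shape, "", dtype=object)
    out[x < -0.65] = "deep_loss"
    out[(x >= -0.65) & (x < -0.2)] = "loss"
    out[(x >= -0.2) & (x <= 0.2)] = "neutral"
    out[(x > 0.2) & (x <= 0.65)] = "gain"
    out[x > 0.65] = "high_gain"
    if scalar:
        return str(out[0])
    return out


def filter_low_expression(
    dataset: ProteogenomicDataset, quantile: float = 0.10, summary: str = "median"
) -> dict[str, list[str]]:
    """Genes removed per tumor type by the bottom-``quantile`` RNA filter.

    Within each tumor type, genes are summarized by their median (or mean)
    RNA across that type's samples; exactly ``floor(quantile * n_genes)``
    genes are removed, lowest first, with ties broken by gene ID so the
    result is deterministic.  Returns {tumor_type: [removed genes]}.
    """
    if not 0 <= quantile < 1:
        raise DataModelError("quantile must lie in [0, 1)")
    removed: dict[str, list[str]] = {}
    rna = dataset.rna.values
    for ttype in dataset.tumor_types:
        cols = dataset.samples_of_type(ttype)
        sub = rna[cols]
        stat = sub.median(axis=1) if summary == "median" else sub.mean(axis=1)
        k = int(np.floor(quantile * len(stat)))
        order = stat.to_frame("stat").sort_values(["stat", "gene"]).index
        removed[ttype] = list(order[:k])
    return removed


def define_neutral_group(
    dataset: ProteogenomicDataset,
    low: float = -0.2,
    high: float = 0.2,
    min_neutral: int = 5,
) -> pd.DataFrame:
    """Per (tumor type, gene) neutral-group reference medians.

    A sample is neutral for a gene when ``low <= dna log2 ratio <= high``.
    Medians are taken on each layer's native scale.  Genes with fewer than
    ``min_neutral`` neutral samples in a tumor type are flagged
    (``usable=False``) and carry no reference there.
    """
    if low >= high:
        raise DataModelError("neutral band low must be < high")
    records = []
    for ttype in dataset.tumor_types:
        cols = dataset.samples_of_type(ttype)
        dna = dataset.dna.values[cols]
        rna = dataset.rna.values[cols]
        prot = dataset.protein.values[cols]
        neutral = (dna >= low) & (dna <= high)
        n_neutral = neutral.sum(axis=1)
        dna_masked = dna.where(neutral)
        rna_masked = rna.where(neutral)
        prot_masked = prot.where(neutral)
        ref = pd.DataFrame(
            {
                "tumor_type": ttype,
                "n_neutral": n_neutral,
                "neutral_dna": dna_masked.median(axis=1),
                "neutral_rna": rna_masked.median(axis=1),
                "neutral_protein": prot_masked.median(axis=1),
            }
        )
        ref["usable"] = ref["n_neutral"] >= min_neutral
        records.append(ref.reset_index())
    return pd.concat(records, ignore_index=True)


def _layer_l2fc(values: pd.DataFrame, reference: pd.Series, scale: str, layer: str) -> pd.DataFrame:
    if scale == "log2":
        return values.sub(reference, axis=0)
    if ((values <= 0) & values.notna()).any().any():
        raise DataModelError(f"nonpositive linear value in {layer} layer")
    return np.log2(values.div(reference, axis=0))


def compute_log2fc(
    dataset: ProteogenomicDataset,
    references: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format fold-change table from neutral references.

    One row per (tumor_type, gene, sample) for genes with a usable
    reference: dna_l2fc, rna_l2fc, protein_l2fc and the SCNA group of the
    DNA change.  Missing expression propagates to missing l2fc.
    """
    frames = []
    for ttype, ref in references.groupby("tumor_type"):
        ref = ref[ref["usable"]].set_index("gene")
        if ref.empty:
            continue
        cols = dataset.samples_of_type(str(ttype))
        genes = [g for g in dataset.genes if g in ref.index]
        dna = _layer_l2fc(
            dataset.dna.values.loc[genes, cols], ref.loc[genes, "neutral_dna"],
            dataset.dna.scale, "dna",
        )
        rna = _layer_l2fc(
            dataset.rna.values.loc[genes, cols], ref.loc[genes, "neutral_rna"],
            dataset.rna.scale, "rna",
        )
        prot = _layer_l2fc(
            dataset.protein.values.loc[genes, cols], ref.loc[genes, "neutral_protein"],
            dataset.protein.scale, "protein",
        )
        long = pd.DataFrame(
            {
                "tumor_type": str(ttype),
                "gene": np.repeat(genes, len(cols)),
                "sample": np.tile(cols, len(genes)),
                "dna_l2fc": dna.to_numpy().ravel(),
                "rna_l2fc": rna.to_numpy().ravel(),
                "protein_l2fc": prot.to_numpy().ravel(),
            }
        )
        frames.append(long)
    if not frames:
        raise DataModelError("no gene has a usable neutral reference")
    table = pd.concat(frames, ignore_index=True)
    group = np.full(len(table), "", dtype=object)
    finite = np.isfinite(table["dna_l2fc"].to_numpy())
    group[finite] = assign_scna_group(table["dna_l2fc"].to_numpy()[finite])
    table["scna_group"] = group
    return table


def foldchange_pipeline(
    dataset: ProteogenomicDataset, params: FoldChangeParams | None = None
) -> pd.DataFrame:
    """Low-expression filter -> neutral references -> fold-change table."""
    params = params or FoldChangeParams()
    removed = filter_low_expression(
        dataset, params.expression_quantile, params.expression_summary
    )
    refs = define_neutral_group(
        dataset, params.neutral_low, params.neutral_high, params.min_neutral
    )
    drop = pd.Series(False, index=refs.index)
    for ttype, genes in removed.items():
        gene_set = set(genes)
        drop |= (refs["tumor_type"] == ttype) & refs["gene"].isin(gene_set)
    refs = refs[~drop].reset_index(drop=True)
    return compute_log2fc(dataset, refs)
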