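"""Compensation score and bootstrap inference.

The compensation score (CS) of a gene in a sample quantifies how much an
expression layer (RNA or protein) under-responds to the DNA dosage change::

    CS = dna_l2fc - expr_l2fc   when dna_l2fc > 0
    CS = expr_l2fc - dna_l2fc   when dna_l2fc < 0

Positive CS means the expression change is attenuated relative to the DNA
change (buffering); CS is undefined at dna_l2fc == 0 and is only computed
for samples outside the neutral SCNA group.

Group-level inference is bootstrap-based throughout: the median CS of a
cell (layer x SCNA group x gene class x tumor type) is tested against zero
with a one-tailed resampled-median test, complex vs non-complex cells are
compared with a two-tailed resampled median-difference test, and all
p-values of one analysis family are Benjamini–Hochberg adjusted together.
Confidence intervals use the basic bootstrap,
``(2*stat - q_hi, 2*stat - q_lo)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import DataModelError


@dataclass
class BootstrapResult:
    statistic: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    fdr: float | None = None


def compute_compensation_score(dna_l2fc, expr_l2fc):
    """CS for paired DNA and expression log2 fold changes.

    Accepts scalars or arrays.  A zero ``dna_l2fc`` is an error: the score
    is undefined there (such observations belong to the neutral group and
    are excluded upstream).  Missing expression yields missing CS.
    """
    d = np.asarray(dna_l2fc, dtype=float)
    x = np.asarray(expr_l2fc, dtype=float)
    if np.any(d == 0):
        raise DataModelError("compensation score undefined at dna_l2fc == 0")
    cs = np.sign(d) * (d - x)
    if cs.ndim == 0:
        return float(cs)
    return cs


def bootstrap_median_test(
    values,
    n_boot: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> BootstrapResult:
    """One-tailed bootstrap test of H0: median <= 0.

    Resamples the observations with replacement ``n_boot`` times, takes the
    median of each resample, and reports p = (1 + #{bootstrap medians <= 0})
    / (n_boot + 1) together with the basic-bootstrap 95% CI of the median.
    """
    if alternative != "greater":
        raise DataModelError("only alternative='greater' is supported")
    if n_boot < 100:
        raise DataModelError("n_boot must be >= 100")
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise DataModelError("need at least 2 finite values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boot_medians = np.median(vals[idx], axis=1)
    stat = float(np.median(vals))
    q_lo, q_hi = np.quantile(boot_medians, [0.025, 0.975])
    p = (1 + np.count_nonzero(boot_medians <= 0)) / (n_boot + 1)
    return BootstrapResult(
        statistic=stat,
        ci_low=float(2 * stat - q_hi),
        ci_high=float(2 * stat - q_lo),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_difference_test(
    group_a,
    group_b,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Two-tailed bootstrap test of H0: median(a) - median(b) == 0.

    Both groups are independently resampled with replacement in every
    replicate.  The p-value recenters the bootstrap distribution at zero:
    p = 2 * min(P*(stat* - stat >= stat), P*(stat* - stat <= stat)) with the
    (1 + k) / (B + 1) finite-sample correction, capped at 1.
    """
    if n_boot < 100:
        raise DataModelError("n_boot must be >= 100")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise DataModelError("each group needs at least 2 finite values")
    rng = np.random.default_rng(seed)
    boot = np.median(a[rng.integers(0, a.size, (n_boot, a.size))], axis=1) - np.median(
        b[rng.integers(0, b.size, (n_boot, b.size))], axis=1
    )
    stat = float(np.median(a) - np.median(b))
    centered = boot - stat
    p_hi = (1 + np.count_nonzero(centered >= stat)) / (n_boot + 1)
    p_lo = (1 + np.count_nonzero(centered <= stat)) / (n_boot + 1)
    p = min(1.0, 2 * min(p_hi, p_lo))
    q_lo, q_hi = np.quantile(boot, [0.025, 0.975])
    return BootstrapResult(
        statistic=stat,
        ci_low=float(2 * stat - q_hi),
        ci_high=float(2 * stat - q_lo),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )


def fdr_adjust(p_values):
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataModelError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compensation_table(
    fc_table: pd.DataFrame, gene_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per gene x sample x layer CS for all non-neutral observations.

    Returns a long table with columns tumor_type, gene, sample, layer
    (rna|protein), scna_group, cs, is_complex, is_ribosomal.
    """
    rows = fc_table[
        fc_table["scna_group"].isin(["deep_loss", "loss", "gain", "high_gain"])
    ].copy()
    if rows.empty:
        raise DataModelError("no non-neutral observations in fold-change table")
    frames = []
    for layer, col in (("rna", "rna_l2fc"), ("protein", "protein_l2fc")):
        part = rows[["tumor_type", "gene", "sample", "scna_group"]].copy()
        part["layer"] = layer
        part["cs"] = compute_compensation_score(
            rows["dna_l2fc"].to_numpy(), rows[col].to_numpy()
        )
        frames.append(part)
    table = pd.concat(frames, ignore_index=True)
    for flag in ("is_complex", "is_ribosomal"):
        if flag in gene_annotation.columns:
            table[flag] = (
                table["gene"].map(gene_annotation[flag]).fillna(False).astype(bool)
            )
    return table.dropna(subset=["cs"]).reset_index(drop=True)


def summarize_group_cs(
    cs_table: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    min_cell_size: int = 20,
    pan_cancer: bool = True,
    class_column: str = "is_complex",
) -> pd.DataFrame:
    """Bootstrap summaries per (layer, SCNA group, gene class, tumor type).

    Each cell gets its median CS, basic-bootstrap CI and one-tailed p
    against zero; each (layer, group, tumor type) pair additionally gets the
    complex-minus-non-complex median-difference test.  All p-values of a
    layer are FDR-adjusted together (one analysis family per
    layer).  Cells below ``min_cell_size`` are reported with missing
    statistics rather than tested.
    """
    if class_column not in cs_table.columns:
        raise DataModelError(f"missing gene-class column {class_column!r}")
    scopes = list(cs_table["tumor_type"].unique())
    if pan_cancer:
        scopes.append("pan")
    records = []
    for layer, layer_tab in cs_table.groupby("layer"):
        for scope in scopes:
            tab = layer_tab if scope == "pan" else layer_tab[layer_tab["tumor_type"] == scope]
            for group, group_tab in tab.groupby("scna_group"):
                in_class = group_tab[group_tab[class_column]]["cs"].to_numpy()
                out_class = group_tab[~group_tab[class_column]]["cs"].to_numpy()
                for label, vals in ((True, in_class), (False, out_class)):
                    rec = {
                        "layer": layer,
                        "tumor_type": scope,
                        "scna_group": group,
                        "gene_class": label,
                        "n": vals.size,
                        "median_cs": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "test": "median_gt_zero",
                    }
                    if vals.size >= min_cell_size:
                        res = bootstrap_median_test(vals, n_boot=n_boot, seed=seed)
                        rec.update(
                            median_cs=res.statistic,
                            ci_low=res.ci_low,
                            ci_high=res.ci_high,
                            p_value=res.p_value,
                        )
                    records.append(rec)
                if in_class.size >= min_cell_size and out_class.size >= min_cell_size:
                    res = bootstrap_difference_test(
                        in_class, out_class, n_boot=n_boot, seed=seed
                    )
                    records.append(
                        {
                            "layer": layer,
                            "tumor_type": scope,
                            "scna_group": group,
                            "gene_class": None,
                            "n": in_class.size + out_class.size,
                            "median_cs": res.statistic,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "p_value": res.p_value,
                            "test": "class_difference",
                        }
                    )
    summary = pd.DataFrame.from_records(records)
    summary["fdr"] = np.nan
    for layer in summary["layer"].unique():
        mask = (summary["layer"] == layer) & summary["p_value"].notna()
        if mask.any():
            summary.loc[mask, "fdr"] = fdr_adjust(summary.loc[mask, "p_value"].to_numpy())
    return summary
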