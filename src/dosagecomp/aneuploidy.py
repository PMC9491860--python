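"""Arm-level aneuploidy scoring and expression–aneuploidy association.

Segments are tiled into fixed-size windows (default 100 kb) within
chromosome-arm boundaries; each arm's log2 ratio is the mean of its
non-missing windows, an arm is called gained when that ratio exceeds +0.2
(strictly) and lost below −0.2, and a sample's aneuploidy score is the
count of gained plus lost arms.

Per-gene association with aneuploidy is estimated by ordinary least
squares, ``expression ~ aneuploidy_score + covariates`` (purity, cell-cycle
score, tumor type, ...); genes are ranked by the t-value of the aneuploidy
coefficient and fed to a preranked gene-set enrichment (weighted
Kolmogorov–Smirnov running sum with gene-label permutation for NES and
FDR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import DataModelError, GeneSetCollection, OmicsMatrix, validate_arms, validate_segments

logger = logging.getLogger(__name__)

GAIN_THRESHOLD = 0.2
LOSS_THRESHOLD = -0.2


def segments_to_windows(
    segments: pd.DataFrame, arms: pd.DataFrame, window_size: int = 100_000
) -> pd.DataFrame:
    """Length-weighted mean log2 ratio per fixed-size window within arms.

    Windows tile each arm from its start ([start, start+w), ...; the last
    window may be short).  A window's value is the coverage-weighted mean of
    the segments overlapping it; windows with no coverage are missing.
    Overlapping segments are resolved by the same length weighting.
    Returns a long frame: sample, chrom, arm, win_start, win_end, log2_ratio.
    """
    if window_size <= 0:
        raise DataModelError("window_size must be positive")
    segments = validate_segments(segments)
    arms = validate_arms(arms)

    # precompute windows per arm
    arm_windows = {}
    for row in arms.itertuples(index=False):
        starts = np.arange(row.start, row.end, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, row.end)
        arm_windows[(row.chrom, row.arm)] = (starts, ends)

    out = []
    for (sample, chrom), seg in segments.groupby(["sample", "chrom"], sort=True):
        s_start = seg["start"].to_numpy()
        s_end = seg["end"].to_numpy()
        s_val = seg["log2_ratio"].to_numpy()
        for (c, arm), (w_start, w_end) in arm_windows.items():
            if c != chrom:
                continue
            # overlap matrix windows x segments
            ov = np.maximum(
                0,
                np.minimum(w_end[:, None], s_end[None, :])
                - np.maximum(w_start[:, None], s_start[None, :]),
            ).astype(float)
            cover = ov.sum(axis=1)
            with np.errstate(invalid="ignore"):
                vals = np.where(cover > 0, (ov * s_val[None, :]).sum(axis=1) / cover, np.nan)
            # windows covered by a single segment carry its value exactly, so
            # strict threshold comparisons are not perturbed by rounding
            single = (ov > 0).sum(axis=1) == 1
            if single.any():
                vals[single] = s_val[ov[single].argmax(axis=1)]
            out.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chrom": c,
                        "arm": arm,
                        "win_start": w_start,
                        "win_end": w_end,
                        "log2_ratio": vals,
                    }
                )
            )
    if not out:
        cols = ["sample", "chrom", "arm", "win_start", "win_end", "log2_ratio"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def windows_to_arm_calls(
    windows: pd.DataFrame, arms: pd.DataFrame, min_window_frac: float = 0.5
) -> pd.DataFrame:
    """Arm-level log2 ratio and gain/loss/neutral call per sample.

    The arm ratio is the mean over non-missing windows; arms whose covered
    window fraction is below ``min_window_frac`` get a missing call.  Calls
    use strict thresholds: gain iff ratio > 0.2, loss iff ratio < −0.2.
    """
    arms = validate_arms(arms)
    rows = []
    for (sample, chrom, arm), grp in windows.groupby(["sample", "chrom", "arm"], sort=True):
        total = len(grp)
        covered = grp["log2_ratio"].notna().sum()
        if total == 0 or covered / total < min_window_frac:
            ratio, call = np.nan, ""
        else:
            vals = grp["log2_ratio"].dropna().to_numpy()
            # constant arms keep their exact value (robust strict thresholds)
            ratio = float(vals[0]) if np.all(vals == vals[0]) else float(vals.mean())
            call = "gain" if ratio > GAIN_THRESHOLD else ("loss" if ratio < LOSS_THRESHOLD else "neutral")
        rows.append(
            {"sample": sample, "chrom": chrom, "arm": arm, "arm_log2_ratio": ratio, "call": call}
        )
    return pd.DataFrame(rows)


def compute_aneuploidy_score(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample aneuploidy score: count of gained plus lost arms.

    Arms with a missing call contribute nothing.
    """
    if calls.empty:
        raise DataModelError("no arm calls")
    rows = []
    for sample, grp in calls.groupby("sample", sort=True):
        gained = int((grp["call"] == "gain").sum())
        lost = int((grp["call"] == "loss").sum())
        rows.append(
            {
                "sample": sample,
                "aneuploidy_score": gained + lost,
                "n_arms_gained": gained,
                "n_arms_lost": lost,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def aneuploidy_from_segments(
    segments: pd.DataFrame, arms: pd.DataFrame, window_size: int = 100_000,
    min_window_frac: float = 0.5,
) -> pd.DataFrame:
    """Convenience: segments -> windows -> arm calls -> scores."""
    windows = segments_to_windows(segments, arms, window_size)
    calls = windows_to_arm_calls(windows, arms, min_window_frac)
    return compute_aneuploidy_score(calls)


def compute_cell_cycle_score(rna: OmicsMatrix, gene_list) -> pd.Series:
    """Mean log2 RNA over a cell-cycle gene list, per sample.

    The list is an input (typically ~10 cell-cycle-entry genes); genes
    absent from the matrix are logged and skipped.
    """
    gene_list = [str(g) for g in gene_list]
    log2 = rna.to_log2().values
    present = [g for g in gene_list if g in log2.index]
    if not present:
        raise DataModelError("none of the cell-cycle genes are in the RNA matrix")
    missing = sorted(set(gene_list) - set(present))
    if missing:
        logger.warning("cell-cycle score: %d gene(s) absent: %s", len(missing), missing[:5])
    return log2.loc[present].mean(axis=0).rename("cell_cycle_score")


@dataclass
class ModelFit:
    gene: str
    beta_aneuploidy: float
    t_value: float
    p_value: float
    covariates: tuple[str, ...]
    n_samples: int
    degenerate: bool = False


def fit_expression_model(
    y: pd.Series,
    aneuploidy: pd.Series,
    covariates: pd.DataFrame | None = None,
    gene: str = "",
) -> ModelFit:
    """OLS of one gene's expression on the aneuploidy score plus covariates.

    Categorical covariates are expanded to indicator contrasts (first level
    dropped); samples missing any value are dropped listwise.  The t-value
    of the aneuploidy coefficient is the association statistic.  A fit with
    (numerically) zero residual variance is flagged degenerate and reports
    a signed infinite t.
    """
    y = pd.Series(y, dtype=float)
    df = pd.DataFrame({"__y": y, "aneuploidy_score": pd.Series(aneuploidy, dtype=float)})
    cov_names: tuple[str, ...] = ()
    if covariates is not None and len(covariates.columns):
        cov = covariates.copy()
        cat_cols = [c for c in cov.columns if not pd.api.types.is_numeric_dtype(cov[c])]
        if cat_cols:
            cov = pd.get_dummies(cov, columns=cat_cols, drop_first=True, dtype=float)
        cov_names = tuple(covariates.columns)
        df = df.join(cov.astype(float), how="inner")
    df = df.dropna()
    n, p = len(df), df.shape[1] - 1  # p = predictors incl. aneuploidy, excl. intercept
    if n <= p + 2:
        raise DataModelError(f"too few complete samples (n={n}) for {p} predictors")
    if df["aneuploidy_score"].nunique() == 1:
        raise DataModelError("aneuploidy score is constant")
    X = sm.add_constant(df.drop(columns="__y"), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DataModelError("perfect collinearity among predictors")
    fit = sm.OLS(df["__y"], X).fit()
    beta = float(fit.params["aneuploidy_score"])
    resid_var = float(fit.ssr / fit.df_resid) if fit.df_resid > 0 else 0.0
    if resid_var <= np.finfo(float).eps * max(1.0, float(np.var(df["__y"]))):
        return ModelFit(
            gene=gene,
            beta_aneuploidy=beta,
            t_value=float(np.sign(beta) * np.inf) if beta != 0 else 0.0,
            p_value=0.0,
            covariates=cov_names,
            n_samples=n,
            degenerate=True,
        )
    return ModelFit(
        gene=gene,
        beta_aneuploidy=beta,
        t_value=float(fit.tvalues["aneuploidy_score"]),
        p_value=float(fit.pvalues["aneuploidy_score"]),
        covariates=cov_names,
        n_samples=n,
        degenerate=False,
    )


def fit_all_genes(
    expression: OmicsMatrix,
    aneuploidy: pd.Series,
    covariates: pd.DataFrame | None = None,
    gene_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene OLS fits; ``gene_mask`` True removes a gene before fitting
    (e.g. mitochondrial exclusion)."""
    genes = expression.genes
    if gene_mask is not None:
        masked = gene_mask.reindex(genes).fillna(False).astype(bool)
        genes = [g for g in genes if not masked[g]]
    rows = []
    for g in genes:
        try:
            fit = fit_expression_model(
                expression.values.loc[g], aneuploidy, covariates, gene=g
            )
        except DataModelError:
            continue
        rows.append(fit.__dict__)
    if not rows:
        raise DataModelError("no gene could be fit")
    return pd.DataFrame(rows).set_index("gene")


def rank_genes(fits: pd.DataFrame) -> pd.Series:
    """Descending t-value ranking; degenerate fits excluded, ties by gene ID."""
    if fits.empty:
        raise DataModelError("no model fits to rank")
    ok = fits[~fits["degenerate"].astype(bool)] if "degenerate" in fits.columns else fits
    ok = ok[np.isfinite(ok["t_value"])]
    if ok.empty:
        raise DataModelError("all fits are degenerate")
    ordered = ok.assign(__g=ok.index.astype(str)).sort_values(
        ["t_value", "__g"], ascending=[False, True]
    )
    return ordered["t_value"].rename("score")


def _running_sum_es(hit_pos: np.ndarray, weights: np.ndarray, n_total: int) -> float:
    """Signed ES: extreme deviation of the weighted running sum.

    ``hit_pos`` are sorted 0-based ranks of the set's genes; ``weights`` the
    corresponding |score|^w values.  Extremes occur immediately after a hit
    or immediately before one, so only hit positions need inspection.
    """
    n_hit = hit_pos.size
    n_miss = n_total - n_hit
    if n_miss == 0 or n_hit == 0:
        raise DataModelError("gene set covers none or all of the ranked list")
    total_w = weights.sum()
    if total_w == 0:  # all hit scores zero: fall back to equal weights
        weights = np.ones(n_hit)
        total_w = float(n_hit)
    w_cum = np.cumsum(weights) / total_w
    miss_step = 1.0 / n_miss
    j = np.arange(1, n_hit + 1)
    after_hit = w_cum - (hit_pos + 1 - j) * miss_step
    before_hit = np.concatenate([[0.0], w_cum[:-1]]) - (hit_pos - (j - 1)) * miss_step
    hi = after_hit.max()
    lo = min(before_hit.min(), 0.0)
    # |max| == |min| ties (up to rounding) resolve to the positive deviation
    return float(hi if hi >= -lo - 1e-12 else lo)


def preranked_enrichment(
    ranked: pd.Series,
    gene_sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment (weighted KS running sum).

    ``ranked`` maps gene -> score, already sorted descending.  Hits advance
    the running sum by |score|^weight (normalized); misses retreat by
    1/(N − N_hit); the ES is the extreme deviation.  Null ES values come
    from gene-label permutation (random same-size sets), giving the nominal
    p (same-sign tail), the NES (ES / mean same-sign null |ES|), and the
    standard sign-separated permutation FDR.  Sets without any ranked gene,
    or covering the whole list, are skipped with a log entry.
    """
    if ranked.empty:
        raise DataModelError("empty ranked list")
    scores = ranked.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise DataModelError("ranked scores must be finite")
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    genes = ranked.index.to_numpy()[order]
    gene_rank = {g: i for i, g in enumerate(genes)}
    n_total = len(genes)
    abs_w = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)

    results = []
    null_es: list[np.ndarray] = []
    for name, members in gene_sets:
        hit_pos = np.array(sorted(gene_rank[g] for g in members if g in gene_rank))
        if hit_pos.size == 0:
            logger.info("preranked_enrichment: set %s has no ranked gene; skipped", name)
            continue
        if hit_pos.size >= n_total:
            logger.info("preranked_enrichment: set %s covers the whole list; skipped", name)
            continue
        es = _running_sum_es(hit_pos, abs_w[hit_pos], n_total)
        k = hit_pos.size
        perm_pos = np.sort(
            rng.random((n_perm, n_total)).argpartition(k, axis=1)[:, :k], axis=1
        )
        perm_es = np.array(
            [_running_sum_es(pp, abs_w[pp], n_total) for pp in perm_pos]
        )
        same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            extreme = np.abs(perm_es[same_sign]) >= abs(es)
            p = (1 + int(extreme.sum())) / (1 + n_same)
            mean_same = np.abs(perm_es[same_sign]).mean()
            nes = es / mean_same if mean_same > 0 else np.nan
        # leading edge: hits at or before (after, for negative ES) the extreme
        lead = _leading_edge(hit_pos, abs_w[hit_pos], n_total, es)
        results.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p_value": p,
                "n_genes": k,
                "leading_edge": ",".join(genes[i] for i in lead),
                "_perm": perm_es,
            }
        )
    if not results:
        raise DataModelError("no testable gene set")
    out = pd.DataFrame(results).set_index("set")
    out["fdr"] = _permutation_fdr(
        out["nes"].to_numpy(),
        [r for r in out["_perm"]],
    )
    return out.drop(columns="_perm").sort_values("p_value")


def _leading_edge(hit_pos, weights, n_total, es) -> np.ndarray:
    total_w = weights.sum()
    if total_w == 0:
        weights = np.ones(len(hit_pos))
        total_w = float(len(hit_pos))
    w_cum = np.cumsum(weights) / total_w
    miss_step = 1.0 / (n_total - len(hit_pos))
    j = np.arange(1, len(hit_pos) + 1)
    after_hit = w_cum - (hit_pos + 1 - j) * miss_step
    if es >= 0:
        peak = int(np.argmax(after_hit))
        return hit_pos[: peak + 1]
    before_hit = np.concatenate([[0.0], w_cum[:-1]]) - (hit_pos - (j - 1)) * miss_step
    trough = int(np.argmin(before_hit))
    return hit_pos[trough:]


def _permutation_fdr(nes: np.ndarray, perm_es_per_set: list[np.ndarray]) -> np.ndarray:
    """Sign-separated permutation FDR over normalized enrichment scores."""
    perm_nes = []
    for perm in perm_es_per_set:
        pos = perm[perm >= 0]
        neg = perm[perm < 0]
        mean_pos = np.abs(pos).mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        norm = np.where(perm >= 0, perm / mean_pos if mean_pos else np.nan,
                        perm / np.abs(mean_neg) if mean_neg else np.nan)
        perm_nes.append(norm[np.isfinite(norm)])
    all_perm = np.concatenate(perm_nes) if perm_nes else np.array([])
    obs = nes[np.isfinite(nes)]
    fdr = np.full(nes.shape, np.nan)
    for i, v in enumerate(nes):
        if not np.isfinite(v) or all_perm.size == 0:
            continue
        if v >= 0:
            n_pos = int((all_perm >= 0).sum())
            num = (all_perm >= v).sum() / n_pos if n_pos else 1.0
            den = (obs >= v).sum() / max(1, (obs >= 0).sum())
        else:
            n_neg = int((all_perm < 0).sum())
            num = (all_perm <= v).sum() / n_neg if n_neg else 1.0
            den = (obs <= v).sum() / max(1, (obs < 0).sum())
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    return fdr
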