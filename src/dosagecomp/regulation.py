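"""Per-gene regulation inference from cross-layer correlations.

A gene's RNA-level regulation is read from its DNA–RNA Spearman correlation
across samples (high correlation = RNA tracks dosage = weak RNA-level
regulation), and its protein-level regulation from the RNA–protein Spearman
correlation.  Per-tumor-type correlations are averaged (unweighted) into a
pan-cancer profile.  On top of the per-gene profiles this module provides:

* the gene-level density-slope association between the two correlations
  (representative points = per-DNA–RNA-bin argmax of the joint density);
* the two-tailed regulation groups (high-DR/low-RP and low-DR/high-RP at
  opposite 35% quantiles by default);
* pathway-level aggregation by median rho with a table-level association;
* bootstrap contrasts between gene classes (complex membership,
  conservation tertiles, subcellular locations);
* a hypergeometric over-representation test for flat gene sets.

Spearman's rho is computed in-repo (Pearson correlation of average ranks)
so tie handling is explicit and testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError, GeneSetCollection, ProteogenomicDataset
from .compensation import BootstrapResult, bootstrap_difference_test, fdr_adjust
from .foldchange import filter_low_expression


def spearman_rho(x, y, min_pairs: int = 10):
    """Spearman correlation: Pearson of average ranks, explicit tie handling.

    Pairs with a missing value in either vector are dropped first.  A
    constant vector (after pairwise deletion) has no defined rank
    correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataModelError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_pairs:
        raise DataModelError(f"fewer than {min_pairs} complete pairs")
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise DataModelError("constant vector: Spearman rho undefined")
    return float((rx * ry).sum() / denom)


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho per row of two equal-shape matrices (NaN-free rows)."""
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    num = (ra * rb).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def filter_low_dna_variance(
    dataset: ProteogenomicDataset,
    low: float = -0.02,
    high: float = 0.02,
    frac: float = 0.70,
) -> dict[str, list[str]]:
    """Genes removed per tumor type for near-constant DNA copy number.

    A gene is removed in a tumor type when strictly more than ``frac`` of
    that type's samples have ``low < log2 ratio < high``: such genes carry
    almost no dosage signal and only add noise to correlation estimates.
    """
    if not 0 < frac <= 1:
        raise DataModelError("frac must lie in (0, 1]")
    removed: dict[str, list[str]] = {}
    for ttype in dataset.tumor_types:
        cols = dataset.samples_of_type(ttype)
        dna = dataset.dna.values[cols]
        inert = ((dna > low) & (dna < high)).sum(axis=1) / len(cols)
        removed[ttype] = list(dna.index[inert > frac])
    return removed


def gene_regulation_profiles(
    dataset: ProteogenomicDataset,
    min_pairs: int = 10,
    excluded: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """DNA–RNA and RNA–protein Spearman rho per gene.

    Computes per-tumor-type correlations over that type's samples, then the
    pan-cancer profile as the unweighted mean over tumor types that
    contributed (``excluded`` maps tumor type -> genes to skip there).
    Returns a gene-indexed frame with columns ``dr_rho``, ``rp_rho``,
    ``n_tumor_types``, plus ``dr_rho__<type>`` / ``rp_rho__<type>`` columns;
    genes with no contributing tumor type are absent.
    """
    excluded = excluded or {}
    per_type_dr, per_type_rp = {}, {}
    genes = np.array(dataset.genes)
    for ttype in dataset.tumor_types:
        cols = dataset.samples_of_type(ttype)
        if len(cols) < min_pairs:
            continue
        dna = dataset.dna.values[cols].to_numpy()
        rna = dataset.rna.values[cols].to_numpy()
        prot = dataset.protein.values[cols].to_numpy()
        complete = (
            np.isfinite(dna).all(axis=1)
            & np.isfinite(rna).all(axis=1)
            & np.isfinite(prot).all(axis=1)
        )
        dr = np.full(len(genes), np.nan)
        rp = np.full(len(genes), np.nan)
        # fast path for complete rows, per-gene pairwise deletion otherwise
        dr[complete] = _rowwise_spearman(dna[complete], rna[complete])
        rp[complete] = _rowwise_spearman(rna[complete], prot[complete])
        for i in np.nonzero(~complete)[0]:
            for target, a, b in ((dr, dna, rna), (rp, rna, prot)):
                try:
                    target[i] = spearman_rho(a[i], b[i], min_pairs=min_pairs)
                except DataModelError:
                    target[i] = np.nan
        skip = excluded.get(ttype, set())
        if skip:
            mask = np.isin(genes, list(skip))
            dr[mask] = np.nan
            rp[mask] = np.nan
        per_type_dr[ttype] = pd.Series(dr, index=genes)
        per_type_rp[ttype] = pd.Series(rp, index=genes)
    if not per_type_dr:
        raise DataModelError("no tumor type has enough samples for correlation")
    dr_tab = pd.DataFrame(per_type_dr)
    rp_tab = pd.DataFrame(per_type_rp)
    ok = dr_tab.notna() & rp_tab.notna()
    dr_tab, rp_tab = dr_tab.where(ok), rp_tab.where(ok)
    out = pd.DataFrame(
        {
            "dr_rho": dr_tab.mean(axis=1),
            "rp_rho": rp_tab.mean(axis=1),
            "n_tumor_types": ok.sum(axis=1),
        }
    )
    for ttype in dr_tab.columns:
        out[f"dr_rho__{ttype}"] = dr_tab[ttype]
        out[f"rp_rho__{ttype}"] = rp_tab[ttype]
    out = out[out["n_tumor_types"] > 0]
    out.index.name = "gene"
    return out


@dataclass
class RepresentativePoints:
    """Per-bin density-argmax points and their fitted association."""

    points: pd.DataFrame  # columns dr, rp
    slope: float
    intercept: float
    rho: float
    method: str


def density_slope(
    dr,
    rp,
    n_bins: int = 40,
    grid_size: int = 100,
    min_points: int = 200,
    method: str = "kde",
) -> RepresentativePoints:
    """Gene-level association between the two regulation correlations.

    Estimates the joint density f(DR, RP) on a ``grid_size`` x
    ``grid_size`` grid (Gaussian KDE, Scott bandwidth), splits the DR range
    into ``n_bins`` windows, and in each window takes the RP of maximum
    density as that window's representative point.  The OLS slope and
    Spearman rho over the representative points summarize the association.
    Exactly collinear clouds make the KDE covariance singular; a 2-D
    histogram density is used instead (also selectable via
    ``method='histogram'``).
    """
    dr = np.asarray(dr, dtype=float)
    rp = np.asarray(rp, dtype=float)
    keep = np.isfinite(dr) & np.isfinite(rp)
    dr, rp = dr[keep], rp[keep]
    if dr.size < min_points:
        raise DataModelError(f"need at least {min_points} points")
    if np.ptp(dr) == 0 and np.ptp(rp) == 0:
        raise DataModelError("degenerate input: all points identical")

    dr_lo, dr_hi = dr.min(), dr.max()
    rp_lo, rp_hi = rp.min(), rp.max()
    if rp_lo == rp_hi:  # flat cloud: every bin's representative RP is that value
        rp_lo, rp_hi = rp_lo - 0.5, rp_hi + 0.5
    gx = np.linspace(dr_lo, dr_hi, grid_size)
    gy = np.linspace(rp_lo, rp_hi, grid_size)

    density = None
    used = method
    if method == "kde":
        # exactly collinear clouds have a singular covariance: the KDE is
        # degenerate (zero bandwidth along one axis), so use the histogram
        cov = np.cov(np.vstack([dr, rp]))
        cond_ok = np.linalg.det(cov) > 1e-12 * max(cov[0, 0] * cov[1, 1], 1e-300)
        if cond_ok:
            try:
                kde = stats.gaussian_kde(np.vstack([dr, rp]))
                xx, yy = np.meshgrid(gx, gy, indexing="ij")
                density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(
                    grid_size, grid_size
                )
                if not np.isfinite(density).all() or density.max() <= 0:
                    density = None
            except np.linalg.LinAlgError:
                density = None
        if density is None:
            used = "histogram"
    elif method != "histogram":
        raise DataModelError("method must be 'kde' or 'histogram'")
    if density is None:
        density, _, _ = np.histogram2d(dr, rp, bins=[grid_size, grid_size],
                                       range=[[dr_lo, dr_hi], [rp_lo, rp_hi]])
        gx = 0.5 * (np.linspace(dr_lo, dr_hi, grid_size + 1)[:-1]
                    + np.linspace(dr_lo, dr_hi, grid_size + 1)[1:])
        gy = 0.5 * (np.linspace(rp_lo, rp_hi, grid_size + 1)[:-1]
                    + np.linspace(rp_lo, rp_hi, grid_size + 1)[1:])

    edges = np.linspace(dr_lo, dr_hi, n_bins + 1)
    col_bin = np.clip(np.searchsorted(edges, gx, side="right") - 1, 0, n_bins - 1)
    have_data = np.histogram(dr, bins=edges)[0] > 0
    points = []
    for b in range(n_bins):
        cols = np.nonzero(col_bin == b)[0]
        if cols.size == 0 or not have_data[b]:
            continue
        block = density[cols, :]
        ci, ri = np.unravel_index(np.argmax(block), block.shape)
        if block[ci, ri] <= 0:
            continue
        points.append((0.5 * (edges[b] + edges[b + 1]), gy[ri]))
    if len(points) < 3:
        raise DataModelError("too few populated bins for a slope fit")
    pts = pd.DataFrame(points, columns=["dr", "rp"])
    slope, intercept = np.polyfit(pts["dr"], pts["rp"], 1)
    try:
        rho = spearman_rho(pts["dr"], pts["rp"], min_pairs=3)
    except DataModelError:
        rho = np.nan
    return RepresentativePoints(
        points=pts, slope=float(slope), intercept=float(intercept), rho=rho, method=used
    )


@dataclass
class RegulationGroups:
    """Opposite-tail regulation classes and the realized rho cutoffs."""

    group1: list[str]  # high DNA–RNA, low RNA–protein: RNA weakly, protein strongly regulated
    group2: list[str]  # low DNA–RNA, high RNA–protein
    dr_high_cut: float
    dr_low_cut: float
    rp_high_cut: float
    rp_low_cut: float
    q: float


def define_regulation_groups(profiles: pd.DataFrame, q: float = 0.35) -> RegulationGroups:
    """Split genes into the two opposite-regulation tails at quantile ``q``.

    Group 1 = genes at or above the (1-q) DNA–RNA quantile and at or below
    the q RNA–protein quantile; Group 2 mirrors.  Quantiles are type-7
    (linear interpolation); realized cutoffs are reported.
    """
    if not 0 < q < 0.5:
        raise DataModelError("q must lie in (0, 0.5)")
    prof = profiles.dropna(subset=["dr_rho", "rp_rho"])
    if len(prof) < 20:
        raise DataModelError("need at least 20 genes with both correlations")
    dr = prof["dr_rho"].to_numpy()
    rp = prof["rp_rho"].to_numpy()
    dr_hi, dr_lo = np.quantile(dr, [1 - q, q])
    rp_hi, rp_lo = np.quantile(rp, [1 - q, q])
    g1 = prof.index[(dr >= dr_hi) & (rp <= rp_lo)]
    g2 = prof.index[(dr <= dr_lo) & (rp >= rp_hi)]
    return RegulationGroups(
        group1=sorted(g1),
        group2=sorted(g2),
        dr_high_cut=float(dr_hi),
        dr_low_cut=float(dr_lo),
        rp_high_cut=float(rp_hi),
        rp_low_cut=float(rp_lo),
        q=q,
    )


@dataclass
class PathwayRegulationTable:
    table: pd.DataFrame  # per pathway: dr_rho, rp_rho, n_genes, frac_complex
    spearman: float
    spearman_p: float
    pearson: float
    pearson_p: float


def pathway_regulation(
    profiles: pd.DataFrame,
    gene_sets: GeneSetCollection,
    min_pathway_genes: int = 5,
    restrict: str | None = None,
    is_complex: pd.Series | None = None,
) -> PathwayRegulationTable:
    """Median per-pathway regulation correlations and their association.

    ``restrict`` may be 'complex' or 'noncomplex' (requires ``is_complex``
    or an ``is_complex`` column merged into ``profiles``) to check that the
    pathway-level association is not carried by complex membership alone.
    """
    prof = profiles.dropna(subset=["dr_rho", "rp_rho"])
    if restrict is not None:
        if is_complex is None:
            if "is_complex" not in prof.columns:
                raise DataModelError("restriction requires complex membership")
            is_complex = prof["is_complex"]
        flag = is_complex.reindex(prof.index).fillna(False).astype(bool)
        prof = prof[flag] if restrict == "complex" else prof[~flag]
    rows = []
    for name, members in gene_sets:
        hit = prof.index.intersection(members)
        if len(hit) < min_pathway_genes:
            continue
        rec = {
            "pathway": name,
            "dr_rho": float(prof.loc[hit, "dr_rho"].median()),
            "rp_rho": float(prof.loc[hit, "rp_rho"].median()),
            "n_genes": len(hit),
        }
        if is_complex is not None:
            rec["frac_complex"] = float(
                is_complex.reindex(hit).fillna(False).astype(bool).mean()
            )
        elif "is_complex" in prof.columns:
            rec["frac_complex"] = float(prof.loc[hit, "is_complex"].mean())
        rows.append(rec)
    if not rows:
        raise DataModelError("no pathway passes the size threshold")
    table = pd.DataFrame(rows).set_index("pathway")
    n = len(table)
    if n < 3:  # association over <3 pathway points is meaningless
        rho = rho_p = r = r_p = np.nan
    else:
        rho = spearman_rho(table["dr_rho"], table["rp_rho"], min_pairs=3)
        # t-approximation p-value for the table-level Spearman
        if abs(rho) == 1.0:
            rho_p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            rho_p = float(2 * stats.t.sf(abs(t), n - 2))
        r, r_p = stats.pearsonr(table["dr_rho"], table["rp_rho"])
    return PathwayRegulationTable(
        table=table, spearman=rho, spearman_p=rho_p, pearson=float(r), pearson_p=float(r_p)
    )


def group_contrast(
    profiles: pd.DataFrame,
    classes: pd.Series,
    statistic: str = "rp_rho",
    n_boot: int = 10_000,
    seed: int = 0,
    min_class_size: int = 10,
) -> BootstrapResult:
    """Bootstrap median-difference contrast between two gene classes.

    ``classes`` is a boolean Series over genes (True = in-class, e.g.
    complex membership, top conservation tertile, one subcellular
    location); the statistic is median(in-class) - median(out-class).
    """
    if statistic not in profiles.columns:
        raise DataModelError(f"unknown statistic column {statistic!r}")
    flag = classes.reindex(profiles.index)
    prof = profiles[flag.notna()]
    flag = flag.loc[prof.index].astype(bool)
    a = prof.loc[flag, statistic].dropna().to_numpy()
    b = prof.loc[~flag, statistic].dropna().to_numpy()
    if a.size < min_class_size or b.size < min_class_size:
        raise DataModelError(f"each class needs >= {min_class_size} genes")
    return bootstrap_difference_test(a, b, n_boot=n_boot, seed=seed)


def overrepresentation_test(query, reference_set, universe) -> tuple[float, float]:
    """One-sided hypergeometric over-representation of ``reference_set``.

    Returns (upper-tail p of the observed overlap, fold enrichment =
    observed overlap fraction / expected fraction).
    """
    universe = set(universe)
    if not universe:
        raise DataModelError("empty universe")
    query = set(query)
    reference_set = set(reference_set)
    if not query <= universe or not reference_set <= universe:
        raise DataModelError("query and reference must be subsets of the universe")
    M, n, N = len(universe), len(reference_set), len(query)
    k = len(query & reference_set)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    expected = n / M
    fold = (k / N) / expected if N and expected else np.nan
    return p, fold


def enrichment_table(
    query, gene_sets: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation across a collection, BH-adjusted."""
    rows = []
    universe = set(universe)
    for name, members in gene_sets:
        ref = set(members) & universe
        if not ref:
            continue
        p, fold = overrepresentation_test(query, ref, universe)
        rows.append({"set": name, "n_overlap": len(set(query) & ref), "p_value": p, "fold": fold})
    if not rows:
        raise DataModelError("no gene set overlaps the universe")
    tab = pd.DataFrame(rows).set_index("set")
    tab["fdr"] = fdr_adjust(tab["p_value"].to_numpy())
    return tab.sort_values("p_value")


def regulation_pipeline(
    dataset: ProteogenomicDataset,
    expression_quantile: float = 0.10,
    dna_low: float = -0.02,
    dna_high: float = 0.02,
    dna_frac: float = 0.70,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Standard filters + per-gene profiles, with annotation flags merged."""
    removed_expr = filter_low_expression(dataset, expression_quantile)
    removed_dna = filter_low_dna_variance(dataset, dna_low, dna_high, dna_frac)
    excluded = {
        t: set(removed_expr.get(t, [])) | set(removed_dna.get(t, []))
        for t in dataset.tumor_types
    }
    profiles = gene_regulation_profiles(dataset, min_pairs=min_pairs, excluded=excluded)
    for col in ("is_complex", "is_ribosomal", "subcellular_location", "conservation_score"):
        if col in dataset.gene_annotation.columns:
            profiles[col] = dataset.gene_annotation[col].reindex(profiles.index)
    return profiles
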