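"""Synthetic proteogenomic data with known compensation ground truth.

The generative model mirrors the structure the analysis assumes: arm-level
copy-number events propagate to RNA with a gene-specific attenuation
(RNA-level compensation ``c_rna``), and RNA propagates to protein with a
second attenuation (protein-level compensation ``c_prot``)::

    dna(g, s)      = arm log2 ratio of gene g's arm in sample s
    rna_l2fc(g, s) = (1 - c_rna(g)) * dna(g, s) + eps,
                        eps ~ Normal(0, sigma_rna(pathway(g)))
    prot_l2fc(g,s) = (1 - c_prot(g)) * rna_l2fc(g, s) + eta,
                        eta ~ Normal(0, sigma_prot(pathway(g)))

Protein-complex genes default to strong protein-level buffering (high
``c_prot``) with low RNA noise, non-complex genes to the reverse — the
recoverable analogue of the observed complex/non-complex contrast.  Noise
scales are drawn per pathway through a Gaussian copula whose correlation
``pathway_coupling`` controls whether pathways with noisy RNA have quiet or
noisy protein, which in turn sets the sign of the pathway-level association
between DNA–RNA and RNA–protein correlations.

RNA is emitted as linear abundance around a log-normal per-gene baseline
(so the low-expression filter has real work to do); protein is emitted as a
log2 ratio, as TMT-style proteomics delivers it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    DataModelError,
    GeneSetCollection,
    OmicsMatrix,
    ProteogenomicDataset,
    align_dataset,
    validate_arms,
)
from . import io as dcio


def default_arm_table() -> pd.DataFrame:
    """A 39-arm synthetic genome: 22 chromosomes, acrocentric p-arms absent.

    Arm coordinates are compact (8–12 Mb per arm) so that 100 kb windowing
    stays cheap while every arm still spans many windows.
    """
    acrocentric = {"chr13", "chr14", "chr15", "chr21", "chr22"}
    rows = []
    for i in range(1, 23):
        chrom = f"chr{i}"
        if chrom in acrocentric:
            rows.append((chrom, "q", 0, 12_000_000))
        else:
            rows.append((chrom, "p", 0, 8_000_000))
            rows.append((chrom, "q", 8_000_000, 20_000_000))
    return validate_arms(pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe one desk-scale study: three tumor types of 90 samples
    each (cohorts of 80–110 samples per type are typical for this kind of
    proteogenomic study), a 39-arm genome, ~30% protein-complex genes, and
    arm gains/losses in roughly a quarter of arms per sample.
    """

    n_genes: int = 1000
    n_samples_per_type: int = 90
    n_tumor_types: int = 3
    n_pathways: int = 50
    frac_complex: float = 0.30
    frac_ribosomal_of_complex: float = 0.10

    scna_event_rate: float = 0.25
    scna_magnitude_mean: float = 0.5
    scna_magnitude_sd: float = 0.15
    scna_magnitude_min: float = 0.25  # keep events above the ±0.2 calling band
    arm_call_threshold: float = 0.2
    # gene-level measurement noise on the DNA log2 ratio; segments stay
    # noiseless so true arm calls are recoverable exactly
    dna_noise_sd: float = 0.05

    # per-gene compensation fractions: Normal(mean, c_sd) clipped to [0, 1]
    c_rna_complex_mean: float = 0.05
    c_rna_noncomplex_mean: float = 0.25
    c_prot_complex_mean: float = 0.60
    c_prot_noncomplex_mean: float = 0.20
    c_prot_ribosomal_mean: float = 0.95
    c_sd: float = 0.08
    c_rna_fixed: float | None = None  # override: constant c_rna for all genes
    c_prot_fixed: float | None = None  # override: constant c_prot for all genes

    # pathway-indexed noise scales (log2 units), drawn uniform in the ranges
    # below through a Gaussian copula with correlation `pathway_coupling`
    sigma_rna_range: tuple[float, float] = (0.10, 0.50)
    sigma_prot_range: tuple[float, float] = (0.10, 1.00)
    pathway_coupling: float = 0.0
    rna_noise_scale_complex: float = 0.6  # complex genes: quieter RNA
    sigma_fixed: float | None = None  # override: one sigma for both layers (0 = noiseless)

    rna_baseline_log2_mean: float = 5.0
    rna_baseline_log2_sd: float = 1.5
    protein_baseline_sd: float = 0.1

    arm_table: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_complex", "scna_event_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataModelError(f"{name} must lie in [0, 1], got {v}")
        if not -1 <= self.pathway_coupling <= 1:
            raise DataModelError("pathway_coupling must lie in [-1, 1]")
        if self.sigma_fixed is not None and self.sigma_fixed < 0:
            raise DataModelError("sigma_fixed must be >= 0")
        if self.n_genes < self.n_pathways:
            raise DataModelError("n_genes must be >= n_pathways")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("sigma_rna_range", "sigma_prot_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_type * self.n_tumor_types


@dataclass
class GroundTruth:
    """True simulation parameters, for parameter-recovery tests."""

    genes: pd.DataFrame  # arm, pathway, is_complex, is_ribosomal, c_rna, c_prot, sigma_rna, sigma_prot
    samples: pd.DataFrame  # tumor_type, true_aneuploidy, n_arms_gained, n_arms_lost
    arm_ratios: pd.DataFrame  # sample x arm log2 ratio


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, types = [], []
    for t in range(config.n_tumor_types):
        ttype = f"TT{t + 1}"
        for s in range(config.n_samples_per_type):
            ids.append(f"{ttype}_S{s + 1:03d}")
            types.append(ttype)
    return ids, types


def _gene_truth(config: SimulationConfig, arms: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    arm_names = (arms["chrom"] + arms["arm"]).tolist()
    # contiguous blocks of genes per arm, round-robin remainder
    arm_of_gene = np.repeat(
        np.arange(len(arm_names)), int(np.ceil(config.n_genes / len(arm_names)))
    )[: config.n_genes]
    pathway = rng.integers(0, config.n_pathways, size=config.n_genes)
    is_complex = rng.random(config.n_genes) < config.frac_complex
    is_ribosomal = is_complex & (rng.random(config.n_genes) < config.frac_ribosomal_of_complex)

    def draw_c(mean_complex, mean_non, fixed, mean_ribo=None):
        if fixed is not None:
            return np.full(config.n_genes, float(fixed))
        means = np.where(is_complex, mean_complex, mean_non)
        if mean_ribo is not None:
            means = np.where(is_ribosomal, mean_ribo, means)
        return np.clip(rng.normal(means, config.c_sd), 0.0, 1.0)

    c_rna = draw_c(config.c_rna_complex_mean, config.c_rna_noncomplex_mean, config.c_rna_fixed)
    c_prot = draw_c(
        config.c_prot_complex_mean,
        config.c_prot_noncomplex_mean,
        config.c_prot_fixed,
        mean_ribo=config.c_prot_ribosomal_mean,
    )
    return pd.DataFrame(
        {
            "arm": [arm_names[a] for a in arm_of_gene],
            "pathway": [f"PW{p + 1:03d}" for p in pathway],
            "is_complex": is_complex,
            "is_ribosomal": is_ribosomal,
            "c_rna": c_rna,
            "c_prot": c_prot,
        },
        index=pd.Index(genes, name="gene"),
    )


def _pathway_sigmas(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Noise scales per pathway via a Gaussian copula.

    ``pathway_coupling`` is the copula correlation between the RNA and
    protein noise ranks: −1 makes RNA-noisy pathways protein-quiet (and thus
    anti-couples the two regulation layers downstream), +1 couples them.
    """
    names = [f"PW{p + 1:03d}" for p in range(config.n_pathways)]
    if config.sigma_fixed is not None:
        s = float(config.sigma_fixed)
        return pd.DataFrame({"sigma_rna": s, "sigma_prot": s}, index=pd.Index(names, name="pathway"))
    z1 = rng.normal(size=config.n_pathways)
    z_ind = rng.normal(size=config.n_pathways)
    rho = config.pathway_coupling
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z_ind
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    lo_r, hi_r = config.sigma_rna_range
    lo_p, hi_p = config.sigma_prot_range
    return pd.DataFrame(
        {"sigma_rna": lo_r + (hi_r - lo_r) * u1, "sigma_prot": lo_p + (hi_p - lo_p) * u2},
        index=pd.Index(names, name="pathway"),
    )


def simulate_copy_number(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, OmicsMatrix, GroundTruth]:
    """Draw arm-level copy-number events and project them to genes.

    Each sample receives independent Bernoulli(``scna_event_rate``) events
    per arm; an altered arm carries one signed log2 ratio shared by every
    gene on it.  Returns the SEG-like segment table (every arm of every
    sample emitted, neutral arms at ratio 0), the gene-level DNA matrix, and
    the ground truth (including the true aneuploidy score: the count of arms
    whose |log2 ratio| exceeds the calling threshold).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arms = config.arm_table if config.arm_table is not None else default_arm_table()
    arms = validate_arms(arms)
    if arms.empty:
        raise DataModelError("zero arms defined")
    arm_names = (arms["chrom"] + arms["arm"]).tolist()
    n_arms = len(arm_names)

    gene_truth = _gene_truth(config, arms, rng)
    sample_ids, tumor_types = _sample_ids(config)
    n = len(sample_ids)

    events = rng.random((n, n_arms)) < config.scna_event_rate
    magnitude = np.maximum(
        rng.normal(config.scna_magnitude_mean, config.scna_magnitude_sd, (n, n_arms)),
        config.scna_magnitude_min,
    )
    sign = np.where(rng.random((n, n_arms)) < 0.5, 1.0, -1.0)
    ratios = np.where(events, sign * magnitude, 0.0)

    arm_ratios = pd.DataFrame(ratios, index=pd.Index(sample_ids, name="sample"), columns=arm_names)
    called = np.abs(ratios) > config.arm_call_threshold
    gained = (ratios > config.arm_call_threshold).sum(axis=1)
    lost = (ratios < -config.arm_call_threshold).sum(axis=1)
    sample_truth = pd.DataFrame(
        {
            "tumor_type": tumor_types,
            "true_aneuploidy": called.sum(axis=1),
            "n_arms_gained": gained,
            "n_arms_lost": lost,
        },
        index=arm_ratios.index,
    )

    arm_idx = {a: i for i, a in enumerate(arm_names)}
    gene_arm = gene_truth["arm"].map(arm_idx).to_numpy()
    gene_dna = ratios[:, gene_arm].T
    if config.dna_noise_sd > 0:
        gene_dna = gene_dna + rng.normal(0, config.dna_noise_sd, gene_dna.shape)
    dna = OmicsMatrix(
        "dna_log2_ratio",
        "log2",
        pd.DataFrame(gene_dna, index=gene_truth.index, columns=sample_ids),
    )

    seg_rows = []
    for si, s in enumerate(sample_ids):
        for ai in range(n_arms):
            seg_rows.append(
                (s, arms.loc[ai, "chrom"], arms.loc[ai, "start"], arms.loc[ai, "end"], ratios[si, ai])
            )
    segments = pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end", "log2_ratio"])

    truth = GroundTruth(genes=gene_truth, samples=sample_truth, arm_ratios=arm_ratios)
    return segments, dna, truth


def simulate_expression(
    dna: OmicsMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Propagate DNA dosage to RNA and protein under the attenuation model.

    RNA is returned as linear abundance (baseline * 2**l2fc); protein as a
    log2 ratio around a small per-gene baseline offset.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if list(truth.genes.index) != dna.genes:
        raise DataModelError("ground truth and DNA matrix gene lists differ")

    sigmas = _pathway_sigmas(config, rng)
    truth.genes["sigma_rna"] = sigmas.loc[truth.genes["pathway"], "sigma_rna"].to_numpy()
    truth.genes["sigma_prot"] = sigmas.loc[truth.genes["pathway"], "sigma_prot"].to_numpy()
    rna_noise_mult = np.where(
        truth.genes["is_complex"].to_numpy(), config.rna_noise_scale_complex, 1.0
    )
    sigma_rna = truth.genes["sigma_rna"].to_numpy() * rna_noise_mult
    sigma_prot = truth.genes["sigma_prot"].to_numpy()

    d = dna.values.to_numpy()
    n_genes, n_samples = d.shape
    c_rna = truth.genes["c_rna"].to_numpy()[:, None]
    c_prot = truth.genes["c_prot"].to_numpy()[:, None]

    rna_l2fc = (1 - c_rna) * d + rng.normal(0, 1, d.shape) * sigma_rna[:, None]
    prot_l2fc = (1 - c_prot) * rna_l2fc + rng.normal(0, 1, d.shape) * sigma_prot[:, None]

    baseline = rng.normal(config.rna_baseline_log2_mean, config.rna_baseline_log2_sd, n_genes)
    rna_linear = 2.0 ** (baseline[:, None] + rna_l2fc)
    prot_base = rng.normal(0, config.protein_baseline_sd, n_genes)

    rna = OmicsMatrix(
        "rna_abundance",
        "linear",
        pd.DataFrame(rna_linear, index=dna.values.index, columns=dna.values.columns),
    )
    protein = OmicsMatrix(
        "protein_abundance",
        "log2",
        pd.DataFrame(
            prot_base[:, None] + prot_l2fc, index=dna.values.index, columns=dna.values.columns
        ),
    )
    return rna, protein


def _annotations(truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator):
    locs = np.array(
        ["nucleus", "nucleoli", "cytoplasm", "mitochondria", "ER",
         "plasma_membrane", "proteasome", "ribosome", "other"]
    )
    gene_ann = pd.DataFrame(
        {
            "is_complex": truth.genes["is_complex"],
            "is_ribosomal": truth.genes["is_ribosomal"],
            "pathway": truth.genes["pathway"],
            "subcellular_location": np.where(
                truth.genes["is_ribosomal"], "ribosome", rng.choice(locs, size=len(truth.genes))
            ),
            # conservation tracks complex membership, so the conservation
            # contrast has recoverable signal
            "conservation_score": rng.normal(0, 1, len(truth.genes))
            + 0.5 * truth.genes["is_complex"].to_numpy(),
        },
        index=truth.genes.index,
    )
    sample_ann = pd.DataFrame(
        {
            "tumor_type": truth.samples["tumor_type"],
            "purity": np.round(rng.uniform(0.5, 0.95, len(truth.samples)), 4),
            "genome_doubled": False,
        },
        index=truth.samples.index,
    )
    return gene_ann, sample_ann


def pathway_gene_sets(truth: GroundTruth) -> GeneSetCollection:
    """Ground-truth pathway membership as a GMT-style collection."""
    sets = {
        pw: sorted(idx)
        for pw, idx in truth.genes.groupby("pathway").groups.items()
    }
    return GeneSetCollection({k: list(map(str, v)) for k, v in sets.items()},
                             {k: "synthetic pathway" for k in sets})


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ProteogenomicDataset, GroundTruth, pd.DataFrame]:
    """Full synthetic cohort: dataset, ground truth, and segment table."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": int(seed)})
    rng = np.random.default_rng(config.seed)
    segments, dna, truth = simulate_copy_number(config, rng)
    rna, protein = simulate_expression(dna, truth, config, rng)
    gene_ann, sample_ann = _annotations(truth, config, rng)
    dataset = align_dataset(dna, rna, protein, gene_ann, sample_ann)
    return dataset, truth, segments


def write_fixture(
    dataset: ProteogenomicDataset,
    truth: GroundTruth,
    segments: pd.DataFrame,
    out_dir,
    arm_table: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the complete file fixture consumable by the CLI.

    Emits the three matrices, segments, arm table, annotations, the
    ground-truth pathway GMT, and two truth tables; returns the paths.
    """
    out = dcio.ensure_out_dir(out_dir)
    arms = arm_table if arm_table is not None else default_arm_table()
    paths = {
        "dna.tsv": lambda p: dcio.write_omics_matrix(dataset.dna, p),
        "rna.tsv": lambda p: dcio.write_omics_matrix(dataset.rna, p),
        "protein.tsv": lambda p: dcio.write_omics_matrix(dataset.protein, p),
        "segments.tsv": lambda p: dcio.write_segments(segments, p),
        "arms.tsv": lambda p: dcio.write_arm_table(arms, p),
        "gene_annotation.tsv": lambda p: dcio.write_gene_annotation(dataset.gene_annotation, p),
        "sample_annotation.tsv": lambda p: dcio.write_sample_annotation(dataset.sample_annotation, p),
        "pathways.gmt": lambda p: dcio.write_gene_sets(pathway_gene_sets(truth), p),
        "truth_genes.tsv": lambda p: truth.genes.to_csv(p, sep="\t", float_format=dcio.FLOAT_FMT),
        "truth_samples.tsv": lambda p: truth.samples.to_csv(p, sep="\t", float_format=dcio.FLOAT_FMT),
    }
    written = []
    for name, writer in paths.items():
        path = out / name
        writer(path)
        written.append(path)
    return written
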