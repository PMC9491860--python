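"""Core data structures shared across the pipeline.

The central object is :class:`ProteogenomicDataset`: three gene x sample
abundance matrices (DNA log2 copy-number ratio, RNA abundance, protein
abundance) aligned on a common gene and sample index, plus per-gene and
per-sample annotation tables.  Matrices are thin wrappers around pandas
DataFrames carrying a declared ``layer`` and measurement ``scale`` so that
downstream fold-change arithmetic never has to guess whether a value is a
linear abundance or already a log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LAYERS = ("dna_log2_ratio", "rna_abundance", "protein_abundance")
SCALES = ("linear", "log2")

SUBCELLULAR_LOCATIONS = (
    "nucleus",
    "nucleoli",
    "cytoplasm",
    "mitochondria",
    "ER",
    "plasma_membrane",
    "proteasome",
    "ribosome",
    "other",
)


class DataModelError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class OmicsMatrix:
    """A gene x sample abundance matrix for one molecular layer.

    Parameters
    ----------
    layer:
        One of ``dna_log2_ratio``, ``rna_abundance``, ``protein_abundance``.
    scale:
        ``linear`` (raw abundances, e.g. FPKM) or ``log2`` (log2 ratios,
        e.g. TMT protein ratios or copy-number log ratios).  The DNA layer
        must always be ``log2``.
    values:
        DataFrame indexed by gene, columns are samples; NaN marks missing.
    """

    layer: str
    scale: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise DataModelError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.scale not in SCALES:
            raise DataModelError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.layer == "dna_log2_ratio" and self.scale != "log2":
            raise DataModelError("dna_log2_ratio layer must have scale='log2'")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample identifiers: {dups[:5]}")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = "gene"

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, genes=None, samples=None) -> "OmicsMatrix":
        """Return a restricted (and reordered) copy."""
        vals = self.values
        if genes is not None:
            vals = vals.loc[list(genes)]
        if samples is not None:
            vals = vals[list(samples)]
        return OmicsMatrix(self.layer, self.scale, vals.copy())

    def to_log2(self) -> "OmicsMatrix":
        """Return the matrix on log2 scale (identity if already log2).

        Linear values must be strictly positive where non-missing.
        """
        if self.scale == "log2":
            return self
        vals = self.values
        if ((vals <= 0) & vals.notna()).any().any():
            raise DataModelError(f"nonpositive linear value in {self.layer} layer")
        return OmicsMatrix(self.layer, "log2", np.log2(vals))


def validate_gene_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a per-gene annotation table.

    Expected columns (all optional except the gene index): ``is_complex``,
    ``is_ribosomal`` (booleans: CORUM-style complex membership), category
    ``subcellular_location``, reals ``conservation_score`` (phyloP-style),
    ``rna_half_life``, and ``pathway``.
    """
    ann = ann.copy()
    if "gene" in ann.columns:
        ann = ann.set_index("gene")
    ann.index = ann.index.astype(str)
    ann.index.name = "gene"
    if ann.index.has_duplicates:
        raise DataModelError("duplicate gene in annotation table")
    for col in ("is_complex", "is_ribosomal"):
        if col in ann.columns:
            ann[col] = ann[col].astype(bool)
    if "subcellular_location" in ann.columns:
        bad = set(ann["subcellular_location"].dropna()) - set(SUBCELLULAR_LOCATIONS)
        if bad:
            raise DataModelError(f"unknown subcellular location(s): {sorted(bad)}")
    return ann


def validate_sample_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample annotation table (tumor_type, purity, ...)."""
    ann = ann.copy()
    if "sample" in ann.columns:
        ann = ann.set_index("sample")
    ann.index = ann.index.astype(str)
    ann.index.name = "sample"
    if ann.index.has_duplicates:
        raise DataModelError("duplicate sample in annotation table")
    if "purity" in ann.columns:
        purity = pd.to_numeric(ann["purity"], errors="coerce")
        out_of_range = purity.dropna()[(purity.dropna() < 0) | (purity.dropna() > 1)]
        if len(out_of_range):
            raise DataModelError("purity outside [0, 1]")
        ann["purity"] = purity
    return ann


def validate_segments(seg: pd.DataFrame) -> pd.DataFrame:
    """Validate a SEG-like table: sample, chrom, start, end, log2_ratio.

    Coordinates are 0-based, half-open [start, end).
    """
    required = ["sample", "chrom", "start", "end", "log2_ratio"]
    missing = [c for c in required if c not in seg.columns]
    if missing:
        raise DataModelError(f"segment table missing column(s): {missing}")
    seg = seg[required].copy()
    seg["sample"] = seg["sample"].astype(str)
    seg["chrom"] = seg["chrom"].astype(str)
    seg["start"] = seg["start"].astype(np.int64)
    seg["end"] = seg["end"].astype(np.int64)
    seg["log2_ratio"] = seg["log2_ratio"].astype(float)
    if (seg["start"] < 0).any():
        raise DataModelError("negative segment coordinate")
    if (seg["start"] >= seg["end"]).any():
        raise DataModelError("segment with start >= end")
    return seg.reset_index(drop=True)


def validate_arms(arms: pd.DataFrame) -> pd.DataFrame:
    """Validate a chromosome-arm definition table: chrom, arm, start, end."""
    required = ["chrom", "arm", "start", "end"]
    missing = [c for c in required if c not in arms.columns]
    if missing:
        raise DataModelError(f"arm table missing column(s): {missing}")
    arms = arms[required].copy()
    arms["chrom"] = arms["chrom"].astype(str)
    arms["arm"] = arms["arm"].astype(str)
    bad_arm = set(arms["arm"]) - {"p", "q"}
    if bad_arm:
        raise DataModelError(f"arm labels must be p/q, got {sorted(bad_arm)}")
    arms["start"] = arms["start"].astype(np.int64)
    arms["end"] = arms["end"].astype(np.int64)
    if (arms["start"] < 0).any():
        raise DataModelError("negative arm coordinate")
    if (arms["start"] >= arms["end"]).any():
        raise DataModelError("arm with start >= end")
    for _, grp in arms.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["end"].shift().dropna().to_numpy() > g["start"].to_numpy()[1:]).any():
            raise DataModelError("overlapping arms within one chromosome")
    if arms.duplicated(subset=["chrom", "arm"]).any():
        raise DataModelError("duplicate chrom/arm pair")
    return arms.reset_index(drop=True)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise DataModelError(f"empty gene set {name!r}")
            self.sets[name] = list(dict.fromkeys(members))  # dedupe, keep order

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def filtered(self, min_size: int, max_size: int) -> "GeneSetCollection":
        keep = {n: m for n, m in self.sets.items() if min_size <= len(m) <= max_size}
        return GeneSetCollection(
            keep, {n: d for n, d in self.descriptions.items() if n in keep}
        )


@dataclass
class ProteogenomicDataset:
    """Aligned DNA / RNA / protein matrices plus annotations.

    All three matrices share identical gene and sample index ordering;
    annotation tables are restricted to (and ordered like) those indices.
    """

    dna: OmicsMatrix
    rna: OmicsMatrix
    protein: OmicsMatrix
    gene_annotation: pd.DataFrame
    sample_annotation: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return self.dna.genes

    @property
    def samples(self) -> list[str]:
        return self.dna.samples

    @property
    def tumor_types(self) -> list[str]:
        if "tumor_type" not in self.sample_annotation.columns:
            return ["all"]
        return sorted(self.sample_annotation["tumor_type"].astype(str).unique())

    def samples_of_type(self, tumor_type: str) -> list[str]:
        if "tumor_type" not in self.sample_annotation.columns:
            return self.samples
        mask = self.sample_annotation["tumor_type"].astype(str) == tumor_type
        return list(self.sample_annotation.index[mask])

    def subset(self, genes=None, samples=None) -> "ProteogenomicDataset":
        genes = self.genes if genes is None else list(genes)
        samples = self.samples if samples is None else list(samples)
        return ProteogenomicDataset(
            dna=self.dna.subset(genes, samples),
            rna=self.rna.subset(genes, samples),
            protein=self.protein.subset(genes, samples),
            gene_annotation=self.gene_annotation.loc[genes].copy(),
            sample_annotation=self.sample_annotation.loc[samples].copy(),
        )

    def drop_genome_doubled(self) -> "ProteogenomicDataset":
        """Remove samples flagged as whole-genome doubled.

        Samples with a missing flag are retained.
        """
        if "genome_doubled" not in self.sample_annotation.columns:
            return self
        flag = self.sample_annotation["genome_doubled"]
        keep = [s for s in self.samples if not bool(flag.get(s)) or pd.isna(flag.get(s))]
        return self.subset(samples=keep)


def align_dataset(
    dna: OmicsMatrix,
    rna: OmicsMatrix,
    protein: OmicsMatrix,
    gene_annotation: pd.DataFrame | None = None,
    sample_annotation: pd.DataFrame | None = None,
) -> ProteogenomicDataset:
    """Align the three layers on shared genes and samples.

    Only genes with at least one non-missing value in every layer, and
    samples present in every layer, are retained.  Gene and sample order is
    canonicalized (sorted) so the result is invariant to input ordering.
    """
    by_layer = {"dna_log2_ratio": dna, "rna_abundance": rna, "protein_abundance": protein}
    for want, mat in by_layer.items():
        if mat.values.empty:
            raise DataModelError(f"empty {want} matrix")
        if mat.layer != want:
            raise DataModelError(f"expected layer {want}, got {mat.layer}")

    samples = sorted(set(dna.samples) & set(rna.samples) & set(protein.samples))
    if not samples:
        raise DataModelError("empty intersection of samples across layers")

    def informative(mat: OmicsMatrix) -> set[str]:
        sub = mat.values[samples]
        return set(sub.index[sub.notna().any(axis=1)])

    genes = sorted(informative(dna) & informative(rna) & informative(protein))
    if not genes:
        raise DataModelError("empty intersection of genes across layers")

    if gene_annotation is None:
        gene_annotation = pd.DataFrame(index=pd.Index(genes, name="gene"))
    gene_annotation = validate_gene_annotation(gene_annotation)
    missing_g = [g for g in genes if g not in gene_annotation.index]
    if missing_g:
        gene_annotation = gene_annotation.reindex(gene_annotation.index.union(missing_g))
    gene_annotation = gene_annotation.loc[genes]

    if sample_annotation is None:
        sample_annotation = pd.DataFrame(index=pd.Index(samples, name="sample"))
    sample_annotation = validate_sample_annotation(sample_annotation)
    missing_s = [s for s in samples if s not in sample_annotation.index]
    if missing_s:
        raise DataModelError(f"samples missing from annotation: {missing_s[:5]}")
    sample_annotation = sample_annotation.loc[samples]

    return ProteogenomicDataset(
        dna=dna.subset(genes, samples),
        rna=rna.subset(genes, samples),
        protein=protein.subset(genes, samples),
        gene_annotation=gene_annotation,
        sample_annotation=sample_annotation,
    )
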