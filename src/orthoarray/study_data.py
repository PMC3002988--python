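"""Probe-level dataset model, tab-separated I/O, and gene-level filters.

The dataset holds normalized log2 hybridization intensities for orthologous
probe sets: every probe maps to one gene and carries the species whose
sequence it was designed from, and every sample is one (species, individual,
time point, treatment class) cell of the study design. All files are
tab-separated text with one header row; the expression matrix is keyed by
probe_id in its first column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIES = ("human", "chimpanzee", "rhesus")
TREATMENTS = ("NS", "LPS")

PROBE_COLUMNS = ["probe_id", "gene_id", "origin_species"]
SAMPLE_COLUMNS = ["sample_id", "species", "individual_id", "time_h", "treatment"]


class DatasetValidationError(ValueError):
    """A dataset file or object violates a structural invariant."""


@dataclass
class ProbeLevelDataset:
    """Probe x sample log2 intensities with probe and sample annotations.

    intensities : DataFrame, index probe_id, columns sample_id (may hold NaN)
    probes      : DataFrame, index probe_id, columns gene_id / origin_species
    samples     : DataFrame, index sample_id, columns species / individual_id
                  / time_h / treatment
    """

    intensities: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if list(self.intensities.index) != list(self.probes.index):
            raise DatasetValidationError(
                "expression rows do not match probe annotation order")
        if list(self.intensities.columns) != list(self.samples.index):
            raise DatasetValidationError(
                "expression columns do not match sample annotation order")
        if self.probes.index.has_duplicates:
            dup = self.probes.index[self.probes.index.duplicated()][0]
            raise DatasetValidationError(f"duplicate probe_id {dup!r}")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise DatasetValidationError(f"duplicate sample_id {dup!r}")
        bad = set(self.probes["origin_species"]) - set(self.samples["species"]) \
            - set(SPECIES)
        if bad:
            raise DatasetValidationError(
                f"unknown probe origin species: {sorted(bad)}")
        counts = self.probes.groupby("gene_id", sort=False).size()
        if (counts > 7).any():
            g = counts[counts > 7].index[0]
            raise DatasetValidationError(
                f"gene {g!r} has {counts[g]} probes; at most 7 allowed")
        key = self.samples[["species", "individual_id", "time_h", "treatment"]]
        if key.duplicated().any():
            row = key[key.duplicated()].iloc[0]
            raise DatasetValidationError(
                f"duplicate design cell {tuple(row)} in sample annotation")
        sp_per_ind = self.samples.groupby("individual_id")["species"].nunique()
        if (sp_per_ind > 1).any():
            ind = sp_per_ind[sp_per_ind > 1].index[0]
            raise DatasetValidationError(
                f"individual {ind!r} is annotated with more than one species")
        bad_t = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise DatasetValidationError(
                f"unknown treatment classes: {sorted(bad_t)}")

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.probes["gene_id"]))

    @property
    def species(self) -> list[str]:
        seen = pd.unique(self.samples["species"])
        return [s for s in SPECIES if s in set(seen)] + \
            [s for s in seen if s not in SPECIES]

    def probe_count(self) -> pd.Series:
        """Probes per gene, in gene order of first appearance."""
        return self.probes.groupby("gene_id", sort=False).size()

    def select_genes(self, genes) -> "ProbeLevelDataset":
        keep = self.probes["gene_id"].isin(set(genes))
        return ProbeLevelDataset(self.intensities.loc[keep.values],
                                 self.probes.loc[keep.values],
                                 self.samples)

    def stratum_samples(self, treatment: str, time_h) -> pd.Index:
        m = (self.samples["treatment"] == treatment) & \
            (self.samples["time_h"] == time_h)
        return self.samples.index[m]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_dataset(expression_path, probe_annot_path, sample_annot_path
                 ) -> ProbeLevelDataset:
    """Read the three tab-separated study files into a validated dataset."""
    probes = pd.read_csv(probe_annot_path, sep="\t", dtype=str)
    _require_columns(probes, PROBE_COLUMNS, probe_annot_path)
    for col in PROBE_COLUMNS:
        bad = probes.index[probes[col].isna()]
        if len(bad):
            raise DatasetValidationError(
                f"{probe_annot_path}: empty {col} on data line {bad[0] + 2}")
    probes = probes.set_index("probe_id")

    samples = pd.read_csv(sample_annot_path, sep="\t", dtype=str)
    _require_columns(samples, SAMPLE_COLUMNS, sample_annot_path)
    samples["time_h"] = samples["time_h"].astype(float)
    samples = samples.set_index("sample_id")

    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.index.name = "probe_id"
    expr.columns.name = "sample_id"

    unknown = expr.index.difference(probes.index)
    if len(unknown):
        row = list(expr.index).index(unknown[0]) + 2
        raise DatasetValidationError(
            f"{expression_path}: probe {unknown[0]!r} on line {row} "
            "is missing from the probe annotation")
    if set(expr.columns) != set(samples.index):
        raise DatasetValidationError(
            "expression columns and sample annotation ids differ")
    return ProbeLevelDataset(expr,
                             probes.loc[expr.index],
                             samples.loc[expr.columns])


def write_dataset(ds: ProbeLevelDataset, expression_path, probe_annot_path,
                  sample_annot_path) -> None:
    ds.intensities.rename_axis("probe_id").to_csv(expression_path, sep="\t")
    ds.probes.rename_axis("probe_id").to_csv(probe_annot_path, sep="\t")
    ds.samples.rename_axis("sample_id").to_csv(sample_annot_path, sep="\t")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# gene-level filters
# ---------------------------------------------------------------------------

def filter_genes_by_probe_support(ds: ProbeLevelDataset, min_probes: int = 3
                                  ) -> ProbeLevelDataset:
    """Keep genes assayed by at least ``min_probes`` orthologous probes.

    The study array carries up to seven probes per gene; genes with fewer
    than three are too thinly measured for the probe-effect models.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    counts = ds.probe_count()
    keep = counts.index[counts >= min_probes]
    if len(keep) == 0:
        warnings.warn("probe-support filter removed every gene", stacklevel=2)
    return ds.select_genes(keep)


def flag_expressed_genes(ds: ProbeLevelDataset, threshold: float = 7.5
                         ) -> set[str]:
    """Genes whose mean intensity exceeds ``threshold`` in >=1 stratum.

    A stratum is one (species, time point, treatment class) cell; the mean is
    over the gene's probes and the stratum's individuals. The returned set is
    the background universe for enrichment analyses.
    """
    if ds.intensities.empty:
        raise ValueError("dataset is empty")
    long = ds.intensities.T  # samples x probes
    key = pd.Series(list(zip(ds.samples["species"], ds.samples["time_h"],
                             ds.samples["treatment"])), index=long.index)
    stratum_mean = long.groupby(key, sort=False).mean()  # stratum x probes
    gene_of = ds.probes["gene_id"]
    per_gene = stratum_mean.T.groupby(gene_of, sort=False).mean()
    hit = (per_gene > threshold).any(axis=1)
    return set(hit.index[hit])


def genes_with_excess_missingness(ds: ProbeLevelDataset, ceiling: float = 0.2
                                  ) -> set[str]:
    """Genes whose missing-value fraction exceeds ``ceiling`` in any stratum.

    These are excluded from model fitting so the near-balanced design
    assumptions of the likelihood machinery stay valid.
    """
    miss = ds.intensities.isna().T  # samples x probes
    key = pd.Series(list(zip(ds.samples["species"], ds.samples["time_h"],
                             ds.samples["treatment"])), index=miss.index)
    frac = miss.groupby(key, sort=False).mean()  # stratum x probes
    gene_of = ds.probes["gene_id"]
    per_gene = frac.T.groupby(gene_of, sort=False).mean()
    bad = (per_gene > ceiling).any(axis=1)
    return set(bad.index[bad])


# ---------------------------------------------------------------------------
# gene sets (GMT-like)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with per-term descriptions (GMT dialect)."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, genes in self.sets.items():
            if not genes:
                raise DatasetValidationError(f"gene set {term!r} is empty")

    def __len__(self):
        return len(self.sets)

    def restrict(self, universe) -> tuple["GeneSetCollection", dict[str, set]]:
        """Intersect with a gene universe; return (collection, unmapped)."""
        universe = set(universe)
        kept, unmapped = {}, {}
        for term, genes in self.sets.items():
            inside = genes & universe
            out = genes - universe
            if out:
                unmapped[term] = set(out)
            if inside:
                kept[term] = frozenset(inside)
        coll = GeneSetCollection(
            kept, {t: self.descriptions.get(t, "") for t in kept})
        return coll, unmapped


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT-like file: term_id <tab> description <tab> gene ids..."""
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                raise DatasetValidationError(
                    f"{path}: empty line {lineno} in gene-set file")
            parts = line.split("\t")
            if len(parts) < 3:
                raise DatasetValidationError(
                    f"{path}: line {lineno} has no genes")
            term, description, genes = parts[0], parts[1], parts[2:]
            if term in sets:
                raise DatasetValidationError(
                    f"{path}: duplicate term {term!r} on line {lineno}")
            sets[term] = frozenset(g for g in genes if g)
            desc[term] = description
    return GeneSetCollection(sets, desc)


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, genes in coll.sets.items():
            fh.write("\t".join([term, coll.descriptions.get(term, "")]
                               + sorted(genes)) + "\n")
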