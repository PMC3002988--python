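"""Hypergeometric gene-set enrichment and chi-square contingency analyses.

Enrichment follows the annotation-driven scheme used for GO / KEGG style
terms: for each term, the upper-tail hypergeometric probability of drawing
at least the observed overlap when sampling the target set from the
expressed-gene background, with Benjamini-Hochberg adjustment across terms.
The contingency analyses cover (a) conservation of the response by
functional category — universal vs bacterial-specific vs viral-specific TLR
response genes, cross-tabulated against how many species shared the
response — and (b) over-representation of marker sets (disease-associated
or HIV-1-interacting genes) among species-specific responders, as Pearson
chi-square tests without continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interspecies_model import bh_fdr
from .study_data import GeneSetCollection

__all__ = ["ContingencyResult", "hypergeometric_enrichment",
           "conservation_by_category", "geneset_overrepresentation_chisq",
           "CONSERVATION_BINS"]

CONSERVATION_BINS = ("three_species", "two_species", "one_species")
_CATEGORY_PRIORITY = ("universal", "viral", "bacterial")


@dataclass
class ContingencyResult:
    """A chi-square test of independence on an r x c count table."""

    observed: pd.DataFrame
    statistic: float
    dof: int
    p_value: float

    @property
    def proportions(self) -> pd.DataFrame:
        """Row-wise proportions of the observed table."""
        return self.observed.div(self.observed.sum(axis=1), axis=0)


def hypergeometric_enrichment(target, background,
                              terms: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in ``target``.

    ``target`` must be a subset of ``background`` (the expressed-gene
    universe); terms are intersected with the background before testing.
    Returns one row per testable term: overlap, target/term/background
    sizes, p_value and BH FDR across the tested terms.
    """
    target, background = set(target), set(background)
    stray = target - background
    if stray:
        raise ValueError(
            f"target contains {len(stray)} genes outside the background "
            f"(e.g. {sorted(stray)[:3]}); align the universes first")
    restricted, _ = terms.restrict(background)
    N, n = len(background), len(target)
    rows = []
    for term, genes in restricted.sets.items():
        K = len(genes)
        k = len(genes & target)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "overlap", "target_size",
                                      "term_size", "background_size",
                                      "p_value"]).set_index("term_id")
    out["fdr"] = bh_fdr(out["p_value"].values) if len(out) else []
    return out.sort_values("p_value")


def _categorize(genes, categories: GeneSetCollection) -> pd.Series:
    """Mutually exclusive category per gene (priority on multi-labels)."""
    order = [t for t in _CATEGORY_PRIORITY if t in categories.sets] + \
        [t for t in categories.sets if t not in _CATEGORY_PRIORITY]
    lab = pd.Series("none", index=pd.Index(sorted(genes), name="gene_id"))
    seen = set()
    for term in order:
        members = categories.sets[term] & set(lab.index)
        dup = members & seen
        if dup:
            warnings.warn(
                f"{len(dup)} genes carry multiple category labels; kept "
                "highest-priority assignment", stacklevel=2)
        fresh = [g for g in members if g not in seen]
        lab.loc[fresh] = term
        seen |= members
    return lab


def conservation_by_category(venn_flags: pd.DataFrame,
                             categories: GeneSetCollection
                             ) -> ContingencyResult:
    """Category x conservation contingency test over responding genes.

    ``venn_flags`` is the output of
    :func:`orthoarray.response_classification.venn_partition`. Responding
    genes are binned by how many species shared the call (three / two /
    one) and cross-tabulated against their category label; homogeneity is
    tested by Pearson chi-square.
    """
    responding = venn_flags.index[venn_flags["venn"] != "none"]
    n_species = venn_flags.loc[responding,
                               venn_flags.columns.intersection(
                                   ["human", "chimpanzee", "rhesus"])
                               ].sum(axis=1)
    bins = pd.cut(n_species, bins=[0.5, 1.5, 2.5, 3.5],
                  labels=list(reversed(CONSERVATION_BINS)))
    cats = _categorize(responding, categories)
    keep = cats != "none"
    table = pd.crosstab(cats[keep], bins[keep].astype(str))
    table = table.reindex(columns=[b for b in CONSERVATION_BINS
                                   if b in table.columns])
    empty = table.index[table.sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"dropping empty categories {list(empty)}",
                      stacklevel=2)
        table = table.drop(index=empty)
    return _chisq(table, correction=False)


def geneset_overrepresentation_chisq(species_specific, marker_set,
                                     expressed_background,
                                     *, correction: bool = False
                                     ) -> ContingencyResult:
    """2x2 chi-square: marker membership vs species-specific response.

    Rows: in / out of the species-specific responder set; columns: in /
    out of the marker set; counts over the expressed background.
    """
    spec = set(species_specific)
    back = set(expressed_background)
    if not spec <= back:
        raise ValueError("species-specific set must lie inside the "
                         "expressed background")
    marker = set(marker_set) & back
    a = len(spec & marker)
    b = len(spec - marker)
    c = len(marker - spec)
    d = len(back) - a - b - c
    table = pd.DataFrame([[a, b], [c, d]],
                         index=["species_specific", "other"],
                         columns=["marker", "non_marker"])
    if not marker:
        warnings.warn("marker set does not intersect the background",
                      stacklevel=2)
        return ContingencyResult(table, 0.0, 1, 1.0)
    return _chisq(table, correction=correction)


def _chisq(table: pd.DataFrame, correction: bool) -> ContingencyResult:
    obs = table.values.astype(float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=correction)
    return ContingencyResult(table, float(stat), int(dof), float(p))
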