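"""Two-tier LPS-response calling, Venn partition, and convergence screen.

A gene is a *primary* responder in a species at a time point when its
treatment FDR falls below a stringent species-specific cutoff and the
absolute log2 effect size clears a species-specific floor (human and rhesus
macaque: FDR < 0.001 and |delta| >= 0.3; chimpanzee: FDR < 0.1 and
|delta| >= 0.1, reflecting that chimpanzee effect sizes run lower overall).
Conditional on a primary call in some species at a time point, the other
species are *rescued* into a secondary call at the same time point when
their nominal p-value is below 0.05 — on the reasoning that a confidently
observed treatment effect in one species makes an effect in the others
likely, so demanding full stringency there would manufacture spurious
species specificity. Rescue is never chained off a secondary call and no
direction agreement is imposed.

Per-species response flags are the union of calls over time points; genes
are then partitioned into the seven species-combination Venn cells
(H = human, C = chimpanzee, R = rhesus macaque).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_data import SPECIES

__all__ = ["CutoffConfig", "primary_calls", "secondary_rescue",
           "venn_partition", "convergence_screen", "VENN_CELLS"]

_LETTER = {"human": "H", "chimpanzee": "C", "rhesus": "R"}
VENN_CELLS = ("HCR", "HC", "HR", "CR", "H-only", "C-only", "R-only", "none")


@dataclass(frozen=True)
class CutoffConfig:
    """Primary (FDR + effect) and secondary (nominal p) calling cutoffs."""

    primary_fdr: dict = field(default_factory=lambda: {
        "human": 0.001, "chimpanzee": 0.1, "rhesus": 0.001})
    primary_effect: dict = field(default_factory=lambda: {
        "human": 0.3, "chimpanzee": 0.1, "rhesus": 0.3})
    secondary_p: float = 0.05

    def __post_init__(self):
        for d in (self.primary_fdr,):
            for sp, v in d.items():
                if not 0 < v <= 1:
                    raise ValueError(f"FDR cutoff for {sp!r} must be in (0,1]")
        for sp, v in self.primary_effect.items():
            if v < 0:
                raise ValueError(f"effect cutoff for {sp!r} must be >= 0")
        if not 0 < self.secondary_p <= 1:
            raise ValueError("secondary p cutoff must be in (0,1]")


def primary_calls(tests: pd.DataFrame, cfg: CutoffConfig | None = None
                  ) -> pd.DataFrame:
    """Add a boolean ``primary`` column to a treatment-test table.

    ``tests`` must carry gene_id, species, time_h, delta_hat, p_value, fdr
    (one row per gene x species x time), as produced by
    :func:`orthoarray.treatment_model.treatment_tests`.
    """
    cfg = cfg or CutoffConfig()
    unknown = set(tests["species"]) - set(cfg.primary_fdr)
    if unknown:
        raise ValueError(f"no cutoffs configured for species {sorted(unknown)}")
    fdr_cut = tests["species"].map(cfg.primary_fdr).astype(float)
    eff_cut = tests["species"].map(cfg.primary_effect).astype(float)
    out = tests.copy()
    out["primary"] = (out["fdr"].values < fdr_cut.values) \
        & (out["delta_hat"].abs().values >= eff_cut.values)
    out["primary"] &= out["fdr"].notna().values
    return out


def secondary_rescue(calls: pd.DataFrame, cfg: CutoffConfig | None = None
                     ) -> pd.DataFrame:
    """Apply the relaxed-p rescue and produce the final call table.

    Adds ``secondary`` and ``call`` ({primary, secondary, none}) columns.
    A species is rescued at a (gene, time point) only when another species
    holds a primary call there; secondary calls themselves never trigger
    further rescue.
    """
    cfg = cfg or CutoffConfig()
    out = calls.copy()
    n_primary = out.groupby(["gene_id", "time_h"])["primary"].transform("sum")
    out["secondary"] = (~out["primary"]) \
        & (n_primary.values > out["primary"].astype(int).values) \
        & (out["p_value"].values < cfg.secondary_p)
    out["secondary"] &= out["p_value"].notna().values
    out["call"] = np.where(out["primary"], "primary",
                           np.where(out["secondary"], "secondary", "none"))
    return out


def venn_partition(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene any-time response flags and Venn category.

    Returns a DataFrame indexed by gene_id with one boolean column per
    species (response at any time point, primary or secondary) and a
    ``venn`` column in {HCR, HC, HR, CR, H-only, C-only, R-only, none}.
    """
    if "call" not in calls.columns:
        raise ValueError("run primary_calls and secondary_rescue first")
    hit = calls.assign(called=calls["call"].isin(["primary", "secondary"]))
    flags = hit.pivot_table(index="gene_id", columns="species",
                            values="called", aggfunc="any", fill_value=False)
    for sp in SPECIES:
        if sp not in flags.columns:
            flags[sp] = False
    flags = flags[list(SPECIES)].astype(bool)

    def cell(row):
        letters = "".join(_LETTER[sp] for sp in SPECIES if row[sp])
        if not letters:
            return "none"
        return letters if len(letters) > 1 else f"{letters}-only"

    flags["venn"] = flags.apply(cell, axis=1)
    return flags


def venn_counts(flags: pd.DataFrame) -> pd.Series:
    """Gene counts per Venn cell, in canonical cell order."""
    counts = flags["venn"].value_counts()
    return counts.reindex(VENN_CELLS, fill_value=0)


def convergence_screen(fits_pre: pd.DataFrame, fits_post: pd.DataFrame,
                       fdr_pre: float = 0.05, p_post: float = 0.05
                       ) -> list[str]:
    """Genes whose species differences vanish after stimulation.

    Selects genes differentially expressed between species before treatment
    (species-LRT FDR < ``fdr_pre`` in the pre-treatment stratum) whose
    post-treatment species-LRT p-value exceeds ``p_post`` — i.e. expression
    converged to practically the same level in all species.
    """
    for name, df in (("pre", fits_pre), ("post", fits_post)):
        for col in ("p_value", "fdr"):
            if col not in df.columns:
                raise ValueError(f"{name}-treatment fit table lacks {col!r}")
    joined = fits_pre[["fdr"]].join(fits_post[["p_value"]],
                                    lsuffix="_pre", how="inner")
    sel = (joined["fdr"] < fdr_pre) & (joined["p_value"] > p_post)
    return list(joined.index[sel])
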