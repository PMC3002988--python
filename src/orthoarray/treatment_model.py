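"""Treatment-response inference: probe correction and per-species tests.

The paired design (non-stimulated and LPS-stimulated cells from the same
individual) is handled in two stages, per time point.

Stage one fits, per gene, the probe-level model

    y_{s,r,i,t} = mu_s + pi_r + kappa_{s,r} + delta·1[LPS]
                  + tau_s·1[LPS] + gamma_{s,i} + eps

by maximum likelihood (random per-individual intercept shared across the
individual's two treatment classes; tau sums to zero over species). Its
probe and attenuation estimates yield the corrected expression

    y*_{s,i,t} = mean_r ( y_{s,r,i,t} - pi_hat_r - kappa_hat_{s,r} ),

a gene-level quantity free of probe composition and cross-species
hybridization artifacts.

Stage two tests, per gene / species / time point, whether treatment shifted
corrected expression. Individual effects shared across the two classes are
eliminated exactly by within-individual differencing, so with m paired
differences d_i the statistic is (m-1)·log(sum d^2 / sum (d - dbar)^2) —
the likelihood ratio with a first-order Bartlett factor — referred to
chi-square with one degree of freedom; the effect size is the mean paired
difference (log2 scale). Benjamini-Hochberg FDR is computed separately for
each (species, time point) over the tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import NonIdentifiableDesignError, build_design
from ._lmm import VAR_FLOOR, fit_random_intercept
from .interspecies_model import bh_fdr
from .study_data import ProbeLevelDataset

__all__ = [
    "TreatmentStageOneFit", "CorrectedExpression", "fit_stage_one",
    "corrected_expression", "compute_corrected_expression",
    "per_species_treatment_lrt", "treatment_tests",
]


@dataclass
class TreatmentStageOneFit:
    """Probe-level treatment-model fit for one gene at one time point."""

    gene_id: str
    time_h: float
    species: list
    probe_ids: list
    mu_hat: np.ndarray
    pi_hat: np.ndarray
    kappa_hat: dict                  # (species, probe_id) -> log2 shift
    treatment_effect: float
    treatment_by_species: np.ndarray  # sum-to-zero deviations, species order
    sigma2_ind: float
    sigma2_eps: float
    loglik: float
    converged: bool
    n_obs: int


@dataclass
class CorrectedExpression:
    """Gene-level probe-corrected expression, one value per design cell."""

    values: pd.DataFrame             # genes x sample_id
    samples: pd.DataFrame            # sample annotation for the columns

    def species_columns(self, species: str, time_h=None) -> pd.Index:
        m = self.samples["species"] == species
        if time_h is not None:
            m &= self.samples["time_h"] == float(time_h)
        return self.samples.index[m]


def fit_stage_one(ds: ProbeLevelDataset, gene_id: str, time_h,
                  *, tol: float = 1e-8, max_iter: int = 200
                  ) -> TreatmentStageOneFit:
    """ML fit of the probe-level treatment model for one gene/time point."""
    time_h = float(time_h)
    m = ds.samples["time_h"] == time_h
    sample_ids = ds.samples.index[m]
    samp = ds.samples.loc[sample_ids]
    by_species = samp.groupby("species")["treatment"].nunique()
    if (by_species < 2).any():
        missing = by_species.index[by_species < 2][0]
        raise ValueError(
            f"species {missing!r} lacks both treatment classes at {time_h} h")

    probe_mask = (ds.probes["gene_id"] == gene_id).values
    if not probe_mask.any():
        raise KeyError(f"unknown gene {gene_id!r}")
    probe_ids = list(ds.probes.index[probe_mask])
    species_names = [s for s in ds.species if s in set(samp["species"])]
    sp_code = {s: i for i, s in enumerate(species_names)}
    origin = np.array([sp_code.get(o, -1)
                       for o in ds.probes.loc[probe_mask, "origin_species"]])
    ind_ids = list(pd.unique(samp["individual_id"]))
    ind_code = {i: j for j, i in enumerate(ind_ids)}

    Y = ds.intensities.loc[probe_mask, sample_ids].values
    R, S = Y.shape
    probe = np.repeat(np.arange(R), S)
    species = np.tile(np.array([sp_code[s] for s in samp["species"]]), R)
    group = np.tile(np.array([ind_code[i] for i in samp["individual_id"]]), R)
    lps = np.tile((samp["treatment"] == "LPS").values, R)
    y = Y.ravel()
    ok = np.isfinite(y)

    info = build_design(species[ok], probe[ok], origin, species_names,
                        lps=lps[ok])
    fit = fit_random_intercept(y[ok], info.X, group[ok],
                               tol=tol, max_iter=max_iter)
    eff = info.unpack(fit.beta)
    kappa = {(species_names[s], probe_ids[r]): float(v)
             for (s, r), v in eff["kappa"].items()}
    return TreatmentStageOneFit(
        gene_id, time_h, species_names, probe_ids, eff["mu"], eff["pi"],
        kappa, eff["treatment"], eff["treatment_by_species"],
        fit.sigma2_ind, fit.sigma2_eps, fit.loglik, fit.converged, fit.n_obs)


def corrected_expression(ds: ProbeLevelDataset, fit: TreatmentStageOneFit
                         ) -> pd.Series:
    """Probe-corrected expression of one gene at the fit's time point.

    Only the probe and attenuation estimates are subtracted before
    averaging over probes; species, treatment and individual signal all
    remain in the corrected values.
    """
    sample_ids = ds.samples.index[ds.samples["time_h"] == fit.time_h]
    samp = ds.samples.loc[sample_ids]
    Y = ds.intensities.loc[fit.probe_ids, sample_ids].values.astype(float)
    correction = np.zeros((len(fit.probe_ids), len(sample_ids)))
    for r, pid in enumerate(fit.probe_ids):
        correction[r, :] = fit.pi_hat[r]
        for j, sp in enumerate(samp["species"]):
            correction[r, j] += fit.kappa_hat.get((sp, pid), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        ystar = np.nanmean(Y - correction, axis=0)
    return pd.Series(ystar, index=sample_ids, name=fit.gene_id)


def compute_corrected_expression(ds: ProbeLevelDataset, time_points=None,
                                 *, tol: float = 1e-8, max_iter: int = 200
                                 ) -> CorrectedExpression:
    """Stage-one fits + correction for every gene at the given time points."""
    if time_points is None:
        time_points = sorted(ds.samples["time_h"].unique())
    pieces = []
    for t in time_points:
        rows = {}
        for gene in ds.gene_ids:
            try:
                fit = fit_stage_one(ds, gene, t, tol=tol, max_iter=max_iter)
            except NonIdentifiableDesignError:
                continue
            rows[gene] = corrected_expression(ds, fit)
        pieces.append(pd.DataFrame(rows).T)
    values = pd.concat(pieces, axis=1)
    return CorrectedExpression(values, ds.samples.loc[values.columns])


def _paired_differences(y_star: CorrectedExpression, species: str, time_h
                        ) -> pd.DataFrame:
    """(LPS - NS) corrected-expression difference per gene x individual."""
    samp = y_star.samples
    m = (samp["species"] == species) & (samp["time_h"] == float(time_h))
    sub = samp.loc[m]
    ns = sub.index[sub["treatment"] == "NS"]
    lp = sub.index[sub["treatment"] == "LPS"]
    ns_by_ind = pd.Series(ns, index=sub.loc[ns, "individual_id"].values)
    lp_by_ind = pd.Series(lp, index=sub.loc[lp, "individual_id"].values)
    inds = ns_by_ind.index.intersection(lp_by_ind.index)
    d = (y_star.values[lp_by_ind[inds]].values
         - y_star.values[ns_by_ind[inds]].values)
    return pd.DataFrame(d, index=y_star.values.index, columns=list(inds))


def per_species_treatment_lrt(y_star: CorrectedExpression, species: str,
                              time_h, *, min_pairs: int = 3,
                              var_floor: float = VAR_FLOOR) -> pd.DataFrame:
    """Treatment LRT (chi2 df=1) per gene for one species and time point.

    Returns a DataFrame indexed by gene with columns delta_hat, lrt,
    p_value, n_pairs, tested. Genes with fewer than ``min_pairs`` complete
    NS/LPS pairs are reported untested.
    """
    D = _paired_differences(y_star, species, time_h)
    vals = D.values
    finite = np.isfinite(vals)
    m = finite.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(np.where(finite, vals, np.nan), axis=1)
        rss0 = np.nansum(np.where(finite, vals, 0.0) ** 2, axis=1)
    rss1 = rss0 - m * np.where(np.isfinite(delta), delta, 0.0) ** 2
    rss1 = np.maximum(rss1, m * var_floor)
    rss0 = np.maximum(rss0, rss1)
    # (m - 1) rather than m: first-order Bartlett factor (exact-variance
    # count after estimating the mean), which keeps the chi2(1) reference
    # honest at the study's small per-species sample sizes
    lrt = (m - 1) * np.log(rss0 / np.maximum(rss1, 1e-300))
    tested = m >= min_pairs
    lrt = np.where(tested, np.maximum(lrt, 0.0), np.nan)
    p = stats.chi2.sf(lrt, df=1)
    out = pd.DataFrame({
        "delta_hat": np.where(tested, delta, np.nan),
        "lrt": lrt, "p_value": p, "n_pairs": m, "tested": tested,
    }, index=D.index)
    out.index.name = "gene_id"
    return out


def treatment_tests(y_star: CorrectedExpression, species=None,
                    time_points=None, *, min_pairs: int = 3) -> pd.DataFrame:
    """All per-(species, time) treatment tests, with FDR per stratum.

    The BH adjustment runs separately within each (species, time point)
    over its tested genes, matching how the classification cutoffs are
    applied downstream.
    """
    samp = y_star.samples
    if species is None:
        seen = set(samp["species"])
        from .study_data import SPECIES
        species = [s for s in SPECIES if s in seen] or sorted(seen)
    if time_points is None:
        time_points = sorted(samp["time_h"].unique())
    frames = []
    for sp in species:
        for t in time_points:
            res = per_species_treatment_lrt(y_star, sp, t,
                                            min_pairs=min_pairs)
            res = res.assign(species=sp, time_h=float(t), fdr=np.nan)
            ok = res["tested"].values & np.isfinite(res["p_value"].values)
            if ok.any():
                res.loc[ok, "fdr"] = bh_fdr(res.loc[ok, "p_value"].values)
            frames.append(res.reset_index())
    cols = ["gene_id", "species", "time_h", "delta_hat", "lrt",
            "p_value", "fdr", "n_pairs", "tested"]
    return pd.concat(frames, ignore_index=True)[cols]
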