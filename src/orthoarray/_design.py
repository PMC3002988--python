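"""Constrained fixed-effect design matrices for the probe-level models.

The mean structure is species mean + probe effect + cross-species
attenuation (+ optional treatment and treatment-by-species terms). Raw
indicator columns are over-parameterized, so estimation runs in the null
space of a linear constraint system:

  * probe effects sum to zero within the gene;
  * attenuation is identically zero on matched (sample species == probe
    origin) pairs — those columns are never created — and its per-species
    means over mismatched probes are equal across species, which anchors
    each species mean to its perfect-match probes while letting a shared
    attenuation level be absorbed;
  * treatment-by-species deviations sum to zero across species.

With these constraints the alternative model of the species test is exactly
full rank on the species x probe cell means, and the null (common mean)
model has two fewer free parameters, giving the chi-square 2-df reference
for the likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space


class NonIdentifiableDesignError(ValueError):
    """The probe origins cannot anchor every species mean."""


@dataclass
class DesignInfo:
    X: np.ndarray                 # reduced (full-column-rank) design
    basis: np.ndarray             # maps reduced coefficients to named ones
    mean_cols: slice
    probe_cols: slice
    kappa_pairs: list             # [(species_code, probe_pos), ...]
    kappa_cols: slice
    treat_col: int | None
    inter_cols: slice | None
    n_species: int
    n_probes: int

    def unpack(self, beta_reduced: np.ndarray) -> dict:
        """Translate reduced-space coefficients into named effects."""
        theta = self.basis @ beta_reduced
        mu = theta[self.mean_cols]
        out = {
            "mu": mu if mu.size > 1 else np.repeat(mu, self.n_species),
            "pi": theta[self.probe_cols],
            "kappa": dict(zip(self.kappa_pairs,
                              theta[self.kappa_cols])),
        }
        if self.treat_col is not None:
            out["treatment"] = float(theta[self.treat_col])
            out["treatment_by_species"] = theta[self.inter_cols]
        return out


def build_design(species: np.ndarray, probe: np.ndarray,
                 origin: np.ndarray, species_names,
                 *, common_mean: bool = False,
                 lps: np.ndarray | None = None) -> DesignInfo:
    """Build the reduced design for one gene's observations.

    species, probe : integer codes per observation
    origin         : per-probe integer species code of the probe's origin
    lps            : optional boolean treatment indicator per observation
    """
    n = species.size
    n_sp = len(species_names)
    n_pr = origin.size

    probes_present = np.unique(probe)
    for s in range(n_sp):
        matched = [r for r in probes_present if origin[r] == s]
        if not matched or not np.any((species == s) & np.isin(probe, matched)):
            raise NonIdentifiableDesignError(
                f"species {species_names[s]!r} has no perfect-match probe "
                "observation; its mean is not identifiable")

    cols = []
    if common_mean:
        cols.append(np.ones((n, 1)))
        mean_cols = slice(0, 1)
        k = 1
    else:
        M = np.zeros((n, n_sp))
        M[np.arange(n), species] = 1.0
        cols.append(M)
        mean_cols = slice(0, n_sp)
        k = n_sp

    P = np.zeros((n, n_pr))
    P[np.arange(n), probe] = 1.0
    cols.append(P)
    probe_cols = slice(k, k + n_pr)
    k += n_pr

    pairs = [(s, r) for s in range(n_sp) for r in probes_present
             if origin[r] != s and np.any((species == s) & (probe == r))]
    K = np.zeros((n, len(pairs)))
    for j, (s, r) in enumerate(pairs):
        K[:, j] = (species == s) & (probe == r)
    cols.append(K)
    kappa_cols = slice(k, k + len(pairs))
    k += len(pairs)

    treat_col = inter_cols = None
    if lps is not None:
        cols.append(lps.astype(float)[:, None])
        treat_col = k
        k += 1
        T = np.zeros((n, n_sp))
        T[np.arange(n), species] = lps.astype(float)
        cols.append(T)
        inter_cols = slice(k, k + n_sp)
        k += n_sp

    X_full = np.hstack(cols)

    # constraint system
    rows = []
    c = np.zeros(k)
    c[probe_cols] = 1.0
    rows.append(c)
    per_species = {s: [j for j, (ss, _) in enumerate(pairs) if ss == s]
                   for s in range(n_sp)}
    have = [s for s in range(n_sp) if per_species[s]]
    for a, b in zip(have[:-1], have[1:]):
        c = np.zeros(k)
        for j in per_species[a]:
            c[kappa_cols.start + j] = 1.0 / len(per_species[a])
        for j in per_species[b]:
            c[kappa_cols.start + j] = -1.0 / len(per_species[b])
        rows.append(c)
    if lps is not None:
        c = np.zeros(k)
        c[inter_cols] = 1.0
        rows.append(c)

    B = null_space(np.vstack(rows)) if rows else np.eye(k)
    return DesignInfo(X_full @ B, B, mean_cols, probe_cols, pairs,
                      kappa_cols, treat_col, inter_cols, n_sp, n_pr)
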