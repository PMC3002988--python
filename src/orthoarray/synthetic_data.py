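"""Synthetic probe-level multi-species expression data with known truth.

The generator emulates the study design of the comparative LPS-response
experiment: three primate species, six individuals each, paired
non-stimulated / LPS-stimulated samples at 4, 12 and 24 hours (108 arrays),
measured on orthologous probe sets of three to seven probes per gene. Each
observation is built from the additive model the inference stages assume:

    y = mu_{g,s} + pi_{g,r} + kappa_{g,s,r} + delta·1[LPS, responder]
        + module latent + gamma_{g,s,i} + eps

where kappa (cross-species hybridization attenuation) applies only when the
sample species differs from the probe's origin species, gamma is a per-gene
individual random intercept, and eps is i.i.d. Gaussian noise. Ground-truth
responder patterns, category labels (universal / bacterial / viral TLR
response), disease and HIV-interaction flags, and planted co-expression
module memberships are returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .study_data import SPECIES, ProbeLevelDataset

__all__ = [
    "ResponderSpec", "ModuleSpec", "SimulationConfig", "TruthTable",
    "make_design", "assign_gene_truth", "simulate_dataset",
    "latent_sd_for_correlation",
]


@dataclass(frozen=True)
class ResponderSpec:
    """One planted class of treatment-responding genes.

    fraction      : share of genes in this class
    delta         : log2 treatment effect (scalar, or {time: delta})
    species       : "all" or tuple of species that may respond
    times         : "all" or tuple of responding time points
    species_probs : optional {species: probability} — each listed species
                    responds independently with this probability (models
                    partially shared responses across species)
    category      : optional fixed category label for the class
    hiv_factor / disease_factor : multiplier on the base flag rates
    """

    name: str
    fraction: float
    delta: float | dict = 1.0
    species: str | tuple = "all"
    times: str | tuple = "all"
    species_probs: dict | None = None
    category: str | None = None
    hiv_factor: float = 1.0
    disease_factor: float = 1.0


@dataclass(frozen=True)
class ModuleSpec:
    """Planted co-expression modules (shared latent factor per module)."""

    n_modules: int = 0
    genes_per_module: int = 10
    latent_sd: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 100
    n_species: int = 3
    n_individuals: int = 6
    time_points: tuple = (4, 12, 24)
    probes_per_gene: tuple = (3, 7)
    baseline_mu: float = 8.0
    baseline_sd: float = 1.0
    species_shift_sd: float = 0.0
    probe_effect_sd: float = 0.5
    attenuation_mean: float = -0.5
    attenuation_sd: float = 0.25
    sigma_individual: float = 0.2
    sigma_noise: float = 0.3
    responders: tuple = ()
    category_fractions: dict = field(default_factory=dict)
    disease_fraction: float = 0.0
    hiv_fraction: float = 0.0
    modules: ModuleSpec = ModuleSpec()
    seed: int = 0

    def __post_init__(self):
        if self.probes_per_gene[0] < 1:
            raise ValueError("probes_per_gene lower bound must be >= 1")
        if not 1 <= self.n_species <= len(SPECIES):
            raise ValueError(f"n_species must be in 1..{len(SPECIES)}")
        for sd in (self.baseline_sd, self.species_shift_sd,
                   self.probe_effect_sd, self.attenuation_sd,
                   self.sigma_individual, self.sigma_noise):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        total = sum(r.fraction for r in self.responders)
        if not 0 <= total <= 1:
            raise ValueError("responder fractions must sum to <= 1")
        for frac in list(self.category_fractions.values()) + \
                [self.disease_fraction, self.hiv_fraction]:
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def species_names(self) -> tuple:
        return SPECIES[: self.n_species]

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class TruthTable:
    """Ground-truth labels for one simulated dataset.

    frame : DataFrame indexed by gene_id with columns responder_class,
            category, disease, hiv, module_id (-1 = none)
    delta : DataFrame indexed by gene_id, MultiIndex columns
            (species, time) holding the true log2 treatment effect
    """

    frame: pd.DataFrame
    delta: pd.DataFrame

    def responders(self, species=None, time=None) -> set[str]:
        d = self.delta
        if species is not None:
            d = d.loc[:, [species]]
        if time is not None:
            d = d.loc[:, pd.IndexSlice[:, time]]
        hit = (d != 0).any(axis=1)
        return set(hit.index[hit])

    def exclusive_responders(self, species) -> set[str]:
        others = set()
        for sp in self.delta.columns.get_level_values(0).unique():
            if sp != species:
                others |= self.responders(species=sp)
        return self.responders(species=species) - others


def make_design(n_species: int = 3, n_individuals: int = 6,
                time_points=(4, 12, 24), classes=("NS", "LPS")
                ) -> pd.DataFrame:
    """Full-factorial sample annotation table of the study design.

    With the study defaults (3 species x 6 individuals x 3 time points x
    {NS, LPS}) this yields 108 sample records, one per hybridized array.
    """
    if min(n_species, n_individuals, len(time_points), len(classes)) < 1:
        raise ValueError("all design dimensions must be >= 1")
    rows = []
    for sp in SPECIES[:n_species]:
        tag = sp[:2]
        for i in range(1, n_individuals + 1):
            ind = f"{tag}{i}"
            for t in time_points:
                for cls in classes:
                    rows.append((f"{ind}_{cls}_{t}h", sp, ind, float(t), cls))
    df = pd.DataFrame(rows, columns=["sample_id", "species", "individual_id",
                                     "time_h", "treatment"])
    return df.set_index("sample_id")


def assign_gene_truth(cfg: SimulationConfig, rng: np.random.Generator
                      ) -> TruthTable:
    """Draw responder classes, categories, flags and module ids per gene."""
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    species = list(cfg.species_names)
    times = [float(t) for t in cfg.time_points]

    frame = pd.DataFrame({
        "responder_class": "", "category": "none",
        "disease": False, "hiv": False, "module_id": -1,
    }, index=pd.Index(genes, name="gene_id"))
    cols = pd.MultiIndex.from_product([species, times],
                                      names=["species", "time_h"])
    delta = pd.DataFrame(0.0, index=frame.index, columns=cols)

    # responder classes on disjoint random gene subsets
    perm = rng.permutation(cfg.n_genes)
    start = 0
    for spec in cfg.responders:
        k = int(round(spec.fraction * cfg.n_genes))
        members = [genes[j] for j in perm[start:start + k]]
        start += k
        frame.loc[members, "responder_class"] = spec.name
        if spec.category is not None:
            frame.loc[members, "category"] = spec.category
        sp_list = species if spec.species == "all" else list(spec.species)
        t_list = times if spec.times == "all" else \
            [float(t) for t in spec.times]
        for g in members:
            for sp in sp_list:
                p = 1.0 if spec.species_probs is None else \
                    spec.species_probs.get(sp, 0.0)
                if p < 1.0 and rng.random() >= p:
                    continue
                for t in t_list:
                    if isinstance(spec.delta, dict):
                        d = spec.delta.get(t, spec.delta.get(int(t), 0.0))
                    else:
                        d = spec.delta
                    delta.loc[g, (sp, t)] = d

    # categories for genes not fixed by their class
    if cfg.category_fractions:
        labels = list(cfg.category_fractions)
        probs = np.array([cfg.category_fractions[c] for c in labels])
        rest = max(0.0, 1.0 - probs.sum())
        draw = rng.choice(labels + ["none"], size=cfg.n_genes,
                          p=np.append(probs, rest))
        free = frame["category"] == "none"
        frame.loc[free, "category"] = draw[free.values]

    # disease / HIV-interaction flags, with per-class rate multipliers
    for col, base, attr in (("disease", cfg.disease_fraction, "disease_factor"),
                            ("hiv", cfg.hiv_fraction, "hiv_factor")):
        if base > 0:
            rate = pd.Series(base, index=frame.index)
            for spec in cfg.responders:
                members = frame.index[frame["responder_class"] == spec.name]
                rate.loc[members] = min(1.0, base * getattr(spec, attr))
            frame[col] = rng.random(cfg.n_genes) < rate.values

    # planted modules, preferentially among non-responders
    ms = cfg.modules
    if ms.n_modules > 0:
        nulls = list(frame.index[frame["responder_class"] == ""])
        pool = nulls if len(nulls) >= ms.n_modules * ms.genes_per_module \
            else genes
        chosen = rng.choice(len(pool), ms.n_modules * ms.genes_per_module,
                            replace=False)
        for m in range(ms.n_modules):
            sel = chosen[m * ms.genes_per_module:(m + 1) * ms.genes_per_module]
            frame.loc[[pool[j] for j in sel], "module_id"] = m
    return TruthTable(frame, delta)


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[ProbeLevelDataset, TruthTable]:
    """Generate one probe-level dataset plus its ground truth.

    The same seed always yields bit-identical output; every random draw
    flows from one ``numpy`` Generator stream.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = assign_gene_truth(cfg, rng)
    samples = make_design(cfg.n_species, cfg.n_individuals,
                          cfg.time_points, ("NS", "LPS"))
    species = list(cfg.species_names)
    sp_idx = np.array([species.index(s) for s in samples["species"]])
    ind_ids = list(pd.unique(samples["individual_id"]))
    ind_idx = np.array([ind_ids.index(i) for i in samples["individual_id"]])
    lps = (samples["treatment"] == "LPS").values
    time_v = samples["time_h"].values
    n_samples = len(samples)

    lo, hi = cfg.probes_per_gene
    n_probes_per_gene = rng.integers(lo, hi + 1, size=cfg.n_genes)

    # module latent factors: one value per (module, sample)
    ms = cfg.modules
    latent = rng.normal(0.0, ms.latent_sd, size=(ms.n_modules, n_samples)) \
        if ms.n_modules > 0 else None

    genes = list(truth.frame.index)
    probe_rows, gene_col, origin_col = [], [], []
    blocks = []
    for gi, g in enumerate(genes):
        R = int(n_probes_per_gene[gi])
        # probe origins cycle the species so every sample species keeps at
        # least one perfect-match probe (as the physical array guarantees)
        origins = [(gi + r) % cfg.n_species for r in range(R)]
        mu = cfg.baseline_mu + rng.normal(0.0, cfg.baseline_sd)
        mu_s = mu + (rng.normal(0.0, cfg.species_shift_sd, cfg.n_species)
                     if cfg.species_shift_sd > 0 else np.zeros(cfg.n_species))
        pi = rng.normal(0.0, cfg.probe_effect_sd, R)
        pi -= pi.mean()  # centered so gene-level species means are defined
        kappa = rng.normal(cfg.attenuation_mean, cfg.attenuation_sd,
                           (cfg.n_species, R))
        for r in range(R):
            kappa[origins[r], r] = 0.0
        gamma = rng.normal(0.0, cfg.sigma_individual, len(ind_ids))
        eps = rng.normal(0.0, cfg.sigma_noise, (R, n_samples))

        d_gene = truth.delta.loc[g]  # (species, time) -> delta
        treat = np.zeros(n_samples)
        if (d_gene != 0).any():
            for j in np.nonzero(lps)[0]:
                treat[j] = d_gene[(species[sp_idx[j]], time_v[j])]

        block = (mu_s[sp_idx][None, :] + pi[:, None]
                 + kappa[sp_idx, :].T + treat[None, :]
                 + gamma[ind_idx][None, :] + eps)
        mid = truth.frame.loc[g, "module_id"]
        if latent is not None and mid >= 0:
            block = block + latent[mid][None, :]
        blocks.append(block)
        for r in range(R):
            probe_rows.append(f"{g}_p{r + 1}")
            gene_col.append(g)
            origin_col.append(species[origins[r]])

    intensities = pd.DataFrame(np.vstack(blocks),
                               index=pd.Index(probe_rows, name="probe_id"),
                               columns=samples.index)
    probes = pd.DataFrame({"gene_id": gene_col, "origin_species": origin_col},
                          index=intensities.index)
    return ProbeLevelDataset(intensities, probes, samples), truth


def latent_sd_for_correlation(rho: float, sigma_individual: float,
                              sigma_noise: float, n_probes: int) -> float:
    """Latent-factor sd giving expected within-module gene-level Pearson rho.

    At the probe-averaged (gene) level the non-shared variance per sample is
    sigma_individual^2 + sigma_noise^2 / n_probes; the shared latent variance
    lambda^2 then satisfies rho = lambda^2 / (lambda^2 + non-shared).
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    resid = sigma_individual ** 2 + sigma_noise ** 2 / n_probes
    return float(np.sqrt(rho / (1.0 - rho) * resid))
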