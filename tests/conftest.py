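import numpy as np
import pandas as pd
import pytest

from orthoarray.study_data import ProbeLevelDataset
from orthoarray.synthetic_data import make_design

SPECIES3 = ("human", "chimpanzee", "rhesus")


def manual_gene_dataset(cell_means, *, pi, kappa=None, n_ind=4,
                        sigma_ind=0.0, sigma_noise=0.0, time_points=(4,),
                        rng=None, gene_id="g1"):
    """Build a one-gene dataset with fully controlled effects.

    cell_means : {species: mean} or {(species, treatment): mean}
    pi         : per-probe effects; probe r's origin species cycles
                 human/chimpanzee/rhesus starting at r=0
    kappa      : {(species, probe_position): attenuation}, zero elsewhere
    """
    rng = rng or np.random.default_rng(0)
    kappa = kappa or {}
    samples = make_design(3, n_ind, time_points)
    R = len(pi)
    origins = [SPECIES3[r % 3] for r in range(R)]
    probe_ids = [f"{gene_id}_p{r}" for r in range(R)]
    ind_ids = list(pd.unique(samples["individual_id"]))
    gamma = {i: rng.normal(0.0, sigma_ind) for i in ind_ids}

    def mean_of(sp, cls):
        if (sp, cls) in cell_means:
            return cell_means[(sp, cls)]
        return cell_means[sp]

    vals = np.empty((R, len(samples)))
    for r in range(R):
        for j, (sid, row) in enumerate(samples.iterrows()):
            sp, cls = row["species"], row["treatment"]
            vals[r, j] = (mean_of(sp, cls) + pi[r]
                          + kappa.get((sp, r), 0.0) + gamma[row["individual_id"]]
                          + rng.normal(0.0, sigma_noise))
    intensities = pd.DataFrame(vals, index=pd.Index(probe_ids, name="probe_id"),
                               columns=samples.index)
    probes = pd.DataFrame({"gene_id": gene_id, "origin_species": origins},
                          index=intensities.index)
    return ProbeLevelDataset(intensities, probes, samples)


def tiny_dataset():
    """Hand-written 3-gene / 6-probe / 4-sample dataset (counts 3, 2, 1)."""
    probes = pd.DataFrame({
        "gene_id": ["gA"] * 3 + ["gB"] * 2 + ["gC"],
        "origin_species": ["human", "chimpanzee", "rhesus",
                           "human", "chimpanzee", "human"],
    }, index=pd.Index([f"p{i}" for i in range(1, 7)], name="probe_id"))
    samples = pd.DataFrame({
        "species": ["human", "human", "chimpanzee", "rhesus"],
        "individual_id": ["h1", "h2", "c1", "r1"],
        "time_h": [4.0, 4.0, 4.0, 4.0],
        "treatment": ["NS", "LPS", "NS", "NS"],
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    rng = np.random.default_rng(42)
    intensities = pd.DataFrame(
        np.round(rng.normal(8.0, 1.0, (6, 4)), 3),
        index=probes.index, columns=samples.index)
    return ProbeLevelDataset(intensities, probes, samples)


@pytest.fixture
def small_dataset():
    return tiny_dataset()
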