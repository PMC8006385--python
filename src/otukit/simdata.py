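"""Synthetic grouped microbiome experiments with known ground truth.

The generator emulates the gross statistical features of a two-group 16S/
shotgun profiling study: a Dirichlet baseline composition shared by both
groups, a designated subset of differentially abundant taxa whose group-2
means are shifted by a known log2 fold change, negative-binomial counts with
mean/dispersion parameterization ``Var = mu + alpha mu^2`` (matching the
differential-abundance model, so parameter recovery is well-posed), and
log-normal library sizes with a stated mean and coefficient of variation.
The effect is applied multiplicatively to the DA taxa without renormalizing
the rest, which keeps the true log2 fold change directly interpretable at the
cost of a small compositional leakage into non-DA taxa.

Every draw flows from the single ``seed``; identical configs produce
identical experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MicrobiomeExperiment, create_experiment
from .errors import ValidationError


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator."""

    n_per_group: tuple[int, int] = (10, 10)
    n_taxa: int = 100
    prop_da: float = 0.0
    log2fc: float = 2.0
    dispersion: float = 0.2
    libsize_mean: float = 1e5
    libsize_cv: float = 0.3
    base_concentration: float = 0.5
    taxonomy_shape: tuple[int, int] = (4, 20)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 2:
            raise ValidationError("n_per_group entries must be >= 2")
        if self.n_taxa < 2:
            raise ValidationError("n_taxa must be >= 2")
        if not 0 <= self.prop_da < 1:
            raise ValidationError("prop_da must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.libsize_mean <= 0 or self.libsize_cv < 0:
            raise ValidationError("invalid library-size parameters")
        if self.base_concentration <= 0:
            raise ValidationError("base_concentration must be > 0")
        n_phyla, n_genera = self.taxonomy_shape
        if not (1 <= n_phyla <= n_genera):
            raise ValidationError("taxonomy_shape must satisfy 1 <= n_phyla <= n_genera")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a simulated experiment."""

    da_taxa: tuple[str, ...]
    true_log2fc: dict[str, float]
    baseline_proportions: pd.Series
    group_labels: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "da_taxa": list(self.da_taxa),
            "true_log2fc": self.true_log2fc,
            "baseline_proportions": self.baseline_proportions.to_dict(),
            "group_labels": self.group_labels.astype(str).to_dict(),
        }


def _sample_library_sizes(rng, n, mean, cv):
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _nb_draw(rng, mean, dispersion):
    """NB with Var = mu + dispersion * mu^2 via numpy's (n, p) form."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _make_taxonomy(rng, taxa_ids, shape):
    n_phyla, n_genera = shape
    genus_of = rng.integers(0, n_genera, size=len(taxa_ids))
    phylum_of_genus = rng.integers(0, n_phyla, size=n_genera)
    return pd.DataFrame(
        {
            "superkingdom": "Bacteria",
            "phylum": [f"Phylum_{phylum_of_genus[g] + 1}" for g in genus_of],
            "genus": [f"Genus_{g + 1}" for g in genus_of],
            "species": list(taxa_ids),
        },
        index=list(taxa_ids),
    )


def _metadata(rng, n1, n2):
    sample_ids = [f"S{i + 1}" for i in range(n1 + n2)]
    groups = pd.Series(["group1"] * n1 + ["group2"] * n2, index=sample_ids,
                       name="group")
    age = pd.Series(rng.normal(40.0, 12.0, size=n1 + n2).round(1),
                    index=sample_ids, name="age")
    return pd.DataFrame({"group": groups, "age": age})


def simulate_experiment(config: SimConfig) -> tuple[MicrobiomeExperiment, SimTruth]:
    """Two-group NB count experiment with designated DA taxa."""
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_per_group
    n = n1 + n2
    taxa = [f"taxon_{i + 1}" for i in range(config.n_taxa)]

    q = rng.dirichlet(np.full(config.n_taxa, config.base_concentration))
    # keep baselines away from hard zero so every taxon can appear
    q = (q + 1e-6) / (q + 1e-6).sum()

    n_da = int(round(config.prop_da * config.n_taxa))
    da_idx = rng.choice(config.n_taxa, size=n_da, replace=False) if n_da else np.array([], int)
    effect = np.ones((config.n_taxa, n))
    effect[np.ix_(da_idx, np.arange(n1, n))] = 2.0**config.log2fc

    lib = _sample_library_sizes(rng, n, config.libsize_mean, config.libsize_cv)
    mu = (q[:, None] * effect) * lib[None, :]
    counts = _nb_draw(rng, mu, config.dispersion)

    metadata = _metadata(rng, n1, n2)
    taxonomy = _make_taxonomy(rng, taxa, config.taxonomy_shape)
    counts_df = pd.DataFrame(counts, index=taxa, columns=metadata.index)
    exp = create_experiment(counts_df, taxonomy=taxonomy, metadata=metadata)
    truth = SimTruth(
        da_taxa=tuple(taxa[i] for i in sorted(da_idx)),
        true_log2fc={taxa[i]: float(config.log2fc) for i in da_idx},
        baseline_proportions=pd.Series(q, index=taxa),
        group_labels=metadata["group"],
    )
    return exp, truth


def simulate_two_cluster_profiles(
    config: SimConfig, divergence: float = 0.5
) -> tuple[MicrobiomeExperiment, SimTruth]:
    """Block community structure: the two groups draw counts around distinct
    Dirichlet baselines blended by ``divergence`` in [0, 1].

    ``divergence = 0`` makes the groups exchangeable (a null construction for
    PERMANOVA calibration); large values separate the group centroids so
    between-group Bray-Curtis exceeds within-group.
    """
    if not 0 <= divergence <= 1:
        raise ValidationError("divergence must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_per_group
    n = n1 + n2
    taxa = [f"taxon_{i + 1}" for i in range(config.n_taxa)]

    conc = np.full(config.n_taxa, config.base_concentration)
    q1 = rng.dirichlet(conc)
    q_other = rng.dirichlet(conc)
    q2 = (1.0 - divergence) * q1 + divergence * q_other
    q1 = (q1 + 1e-6) / (q1 + 1e-6).sum()
    q2 = (q2 + 1e-6) / (q2 + 1e-6).sum()

    lib = _sample_library_sizes(rng, n, config.libsize_mean, config.libsize_cv)
    mu = np.empty((config.n_taxa, n))
    mu[:, :n1] = q1[:, None] * lib[None, :n1]
    mu[:, n1:] = q2[:, None] * lib[None, n1:]
    counts = _nb_draw(rng, mu, config.dispersion)

    metadata = _metadata(rng, n1, n2)
    taxonomy = _make_taxonomy(rng, taxa, config.taxonomy_shape)
    counts_df = pd.DataFrame(counts, index=taxa, columns=metadata.index)
    exp = create_experiment(counts_df, taxonomy=taxonomy, metadata=metadata)
    truth = SimTruth(
        da_taxa=(),
        true_log2fc={},
        baseline_proportions=pd.Series(q1, index=taxa),
        group_labels=metadata["group"],
    )
    return exp, truth
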