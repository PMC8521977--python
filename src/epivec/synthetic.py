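"""A synthetic epidemiological world for end-to-end testing.

The generator emulates a GBD-like incidence table (at full scale, 199
diseases × 195 countries × 20 age bands; far smaller by default) with
known latent structure, so every downstream stage — embedding
aggregation, leave-entity-out splits, the regressor, the metrics and
the embedding-context classifier — can be exercised and checked against
ground truth without licensed data.

The generative model is additive in log10 space with a bilinear
disease×country interaction:

    log10 I(d, c, a) = mu + m_d + m_c + <u_d, v_c> + age_d[a] + eps

where u_d and v_c are latent factor vectors drawn around per-group
centroids (diseases belong to disease groups, countries to clusters,
with between:within spread 4:1 by default so labels are recoverable
from the factors), age_d is a per-disease smooth age profile, and eps
is Gaussian observation noise.  A stated fraction of cells is then
overwritten with exact zeros, uniformly at random, mimicking
missing-or-truly-zero entries.  Synthetic embeddings of tunable
informativeness are linear images of [u; m] mixed with independent
noise: at informativeness 1 the latent structure is exactly linearly
decodable, at 0 the embedding is pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import GroupLabeling
from .dataset import IncidenceTable
from .embeddings import EmbeddingTable

_WORDS = [
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega",
]

DEFAULT_N_DISEASES = 50
DEFAULT_N_COUNTRIES = 30
DEFAULT_N_AGE = 20
DEFAULT_NOISE_SD = 0.1  # log10 units
DEFAULT_BETWEEN_WITHIN_RATIO = 4.0


def _make_names(prefix: str, n: int) -> list[str]:
    """Unique multi-word synthetic names ("disease alpha beta", ...)."""
    names = []
    k = len(_WORDS)
    for i in range(n):
        names.append(f"{prefix} {_WORDS[i % k]} {_WORDS[(i // k) % k]} {i // (k * k)}"
                     if i >= k * k else f"{prefix} {_WORDS[i % k]} {_WORDS[(i // k) % k]}")
    return names


@dataclass
class SyntheticWorld:
    """Latent factors, main effects, age profiles and group labels."""

    disease_names: list
    country_names: list
    disease_factors: np.ndarray  # (n_diseases, q)
    country_factors: np.ndarray  # (n_countries, q)
    disease_main: np.ndarray  # (n_diseases,), log10 units
    country_main: np.ndarray  # (n_countries,), log10 units
    age_profiles: np.ndarray  # (n_diseases, n_age), log10 units
    disease_group: np.ndarray  # labels in 1..G_d
    country_cluster: np.ndarray  # labels in 1..G_c
    mu: float
    seed: int

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_countries(self) -> int:
        return len(self.country_names)

    @property
    def n_age(self) -> int:
        return self.age_profiles.shape[1]

    @property
    def q(self) -> int:
        return self.disease_factors.shape[1]

    def log_incidence(self) -> np.ndarray:
        """Noise-free log10 incidence grid, shape (n_diseases, n_countries, n_age)."""
        interaction = self.disease_factors @ self.country_factors.T
        base = (self.mu + self.disease_main[:, None] + self.country_main[None, :]
                + interaction)
        return base[:, :, None] + self.age_profiles[:, None, :]


def _grouped_factors(rng, n: int, q: int, n_groups: int, between_sd: float,
                     within_sd: float):
    """Group centroids evenly spaced on a randomly oriented circle of radius
    ``between_sd * sqrt(2)``, entities scattered around their centroid.

    The even spacing guarantees a minimum between-centroid distance (Gaussian
    centroids can collide by chance), so the stated between:within contrast is
    actually realized and labels stay recoverable from the factors.
    """
    if n_groups == 1 or q == 1:
        centroids = rng.standard_normal((n_groups, q)) * between_sd
    else:
        basis, _ = np.linalg.qr(rng.standard_normal((q, 2)))
        theta = 2 * np.pi * (np.arange(n_groups) / n_groups + rng.uniform())
        radius = between_sd * np.sqrt(2.0)
        centroids = radius * (np.cos(theta)[:, None] * basis[:, 0]
                              + np.sin(theta)[:, None] * basis[:, 1])
    labels = 1 + (np.arange(n) % n_groups)
    rng.shuffle(labels)
    factors = centroids[labels - 1] + rng.standard_normal((n, q)) * within_sd
    return factors, labels


def make_world(
    n_diseases: int = DEFAULT_N_DISEASES,
    n_countries: int = DEFAULT_N_COUNTRIES,
    n_age: int = DEFAULT_N_AGE,
    q: int = 2,
    n_disease_groups: int = 5,
    n_country_clusters: int = 4,
    seed: int = 0,
    between_within_ratio: float = DEFAULT_BETWEEN_WITHIN_RATIO,
    mu: float = 1.0,
) -> SyntheticWorld:
    """Generate a synthetic world with group-structured latent factors.

    Group centroids are drawn first; each entity's factor is then
    sampled around its group centroid with within-group spread smaller
    than the between-group spread (default ratio 4:1), so group labels
    are linearly recoverable from the factors.  Entities get unique
    multi-word names so the bag-of-words embedding path is exercised.
    """
    for name, val in [("n_diseases", n_diseases), ("n_countries", n_countries),
                      ("n_age", n_age), ("q", q),
                      ("n_disease_groups", n_disease_groups),
                      ("n_country_clusters", n_country_clusters)]:
        if val < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")
    if n_disease_groups > n_diseases:
        raise ValueError("n_disease_groups exceeds n_diseases")
    if n_country_clusters > n_countries:
        raise ValueError("n_country_clusters exceeds n_countries")
    rng = np.random.default_rng(seed)
    between_sd = 1.0
    within_sd = between_sd / between_within_ratio
    disease_factors, disease_group = _grouped_factors(
        rng, n_diseases, q, n_disease_groups, between_sd, within_sd)
    country_factors, country_cluster = _grouped_factors(
        rng, n_countries, q, n_country_clusters, between_sd, within_sd)
    disease_main = rng.standard_normal(n_diseases) * 0.7
    country_main = rng.standard_normal(n_countries) * 0.3
    # smooth per-disease age profile: Gaussian bump at a random peak age
    peaks = rng.uniform(0, n_age - 1, size=n_diseases)
    widths = rng.uniform(n_age / 6, n_age / 2, size=n_diseases)
    amps = rng.uniform(0.2, 0.8, size=n_diseases)
    ages = np.arange(n_age)
    age_profiles = amps[:, None] * np.exp(
        -((ages[None, :] - peaks[:, None]) / widths[:, None]) ** 2)
    age_profiles -= age_profiles.mean(axis=1, keepdims=True)
    return SyntheticWorld(
        disease_names=_make_names("disease", n_diseases),
        country_names=_make_names("country", n_countries),
        disease_factors=disease_factors, country_factors=country_factors,
        disease_main=disease_main, country_main=country_main,
        age_profiles=age_profiles, disease_group=disease_group,
        country_cluster=country_cluster, mu=mu, seed=seed,
    )


def sample_incidence(world: SyntheticWorld, noise_sd: float = DEFAULT_NOISE_SD,
                     zero_rate: float = 0.0, seed: int = 0) -> IncidenceTable:
    """Sample an incidence table from the world's generative model.

    A fraction ``zero_rate`` of cells, chosen uniformly at random, is
    overwritten with exact 0 (emulating missing-or-zero entries); the
    table always has n_diseases × n_countries × n_age rows.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= zero_rate < 1:
        raise ValueError("zero_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    log_inc = world.log_incidence()
    log_inc = log_inc + rng.standard_normal(log_inc.shape) * noise_sd
    incidence = 10.0 ** log_inc
    flat = incidence.reshape(-1)
    n_zero = int(round(zero_rate * flat.size))
    if n_zero:
        zero_idx = rng.choice(flat.size, size=n_zero, replace=False)
        flat[zero_idx] = 0.0
    d_idx, c_idx, a_idx = np.meshgrid(
        np.arange(world.n_diseases), np.arange(world.n_countries),
        np.arange(world.n_age), indexing="ij")
    df = pd.DataFrame({
        "disease": np.asarray(world.disease_names)[d_idx.ravel()],
        "country": np.asarray(world.country_names)[c_idx.ravel()],
        "age_group": a_idx.ravel(),
        "incidence": flat,
    })
    return IncidenceTable(df, n_age=world.n_age)


def derive_embeddings(world: SyntheticWorld, entity: str, dim: int,
                      informativeness: float, seed: int = 0) -> EmbeddingTable:
    """Entity-level embeddings of tunable informativeness.

    Each vector is ``informativeness × L([factors; main]) +
    (1 − informativeness) × noise`` with L a fixed random linear map
    drawn once from the seed.  At informativeness 1 the latent structure
    is exactly linearly decodable from the embedding; at 0 the embedding
    is independent noise.
    """
    if entity not in ("disease", "country"):
        raise ValueError("entity must be 'disease' or 'country'")
    if not 0 <= informativeness <= 1:
        raise ValueError("informativeness must be in [0, 1]")
    q = world.q
    if dim < q + 1:
        raise ValueError(f"dim must be >= q+1 = {q + 1}")
    if entity == "disease":
        base = np.column_stack([world.disease_factors, world.disease_main])
        names = world.disease_names
    else:
        base = np.column_stack([world.country_factors, world.country_main])
        names = world.country_names
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((q + 1, dim)) / np.sqrt(q + 1)
    noise = rng.standard_normal((len(names), dim))
    vectors = informativeness * (base @ L) + (1.0 - informativeness) * noise
    entries = {name: vectors[i].copy() for i, name in enumerate(names)}
    return EmbeddingTable(entries=entries, dim=dim, level="entity",
                          provider_id=f"synthetic-{entity}")


def group_labels(world: SyntheticWorld) -> tuple[GroupLabeling, GroupLabeling]:
    """The world's disease→group and country→cluster labelings, verbatim."""
    diseases = GroupLabeling(
        entity_labels={n: int(g) for n, g in zip(world.disease_names, world.disease_group)},
        kind="disease-group")
    countries = GroupLabeling(
        entity_labels={n: int(g) for n, g in zip(world.country_names, world.country_cluster)},
        kind="country-cluster")
    return diseases, countries
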