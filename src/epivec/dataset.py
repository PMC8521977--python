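"""Incidence-table I/O, preprocessing and feature assembly.

An incidence table holds one record per (disease, country, age group)
with a non-negative incidence rate per 100,000 population.  Age groups
are the twenty 5-year bands 0–4, 5–9, …, 95+, indexed 0–19.  Records
with zero incidence are removed before the base-10 log transform; model
features are the concatenation of a disease embedding, a country
embedding and a one-hot age vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import Provider, normalize_name

#: number of 5-year age bands
N_AGE_DEFAULT = 20


def age_band_labels(n_age: int = N_AGE_DEFAULT) -> list[str]:
    """Labels "0-4", "5-9", ..., last band open-ended ("95+")."""
    labels = [f"{5 * i}-{5 * i + 4}" for i in range(n_age - 1)]
    labels.append(f"{5 * (n_age - 1)}+")
    return labels


def parse_age_label(label: str, n_age: int = N_AGE_DEFAULT) -> int:
    """Map an age band label (or integer index) to its 0-based index.

    Accepts "30-34" (also en-dash), "95+", "95 plus", or a bare index.
    """
    text = str(label).strip().replace("–", "-").replace(" to ", "-")
    text = text.removesuffix(" years").strip()
    lookup = {lab: i for i, lab in enumerate(age_band_labels(n_age))}
    if text in lookup:
        return lookup[text]
    if text.endswith("plus"):
        text2 = text[: -len("plus")].strip() + "+"
        if text2 in lookup:
            return lookup[text2]
    try:
        idx = int(text)
    except ValueError:
        raise ValueError(f"unknown age band label {label!r}") from None
    if not 0 <= idx < n_age:
        raise ValueError(f"age index {idx} out of range [0, {n_age})")
    return idx


@dataclass
class IncidenceTable:
    """Records of (disease, country, age_group, incidence per 100,000).

    Wraps a DataFrame with columns disease, country, age_group (int
    index) and incidence (non-negative float).  Keys are unique.
    """

    df: pd.DataFrame
    n_age: int = N_AGE_DEFAULT

    def __post_init__(self) -> None:
        required = ["disease", "country", "age_group", "incidence"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = self.df[required].copy()
        df["disease"] = df["disease"].map(normalize_name)
        df["country"] = df["country"].map(normalize_name)
        df["age_group"] = df["age_group"].astype(int)
        df["incidence"] = df["incidence"].astype(float)
        if (df["incidence"] < 0).any():
            bad = df.loc[df["incidence"] < 0].iloc[0]
            raise ValueError(
                f"negative incidence for ({bad['disease']}, {bad['country']}, "
                f"{bad['age_group']})"
            )
        out_of_range = ~df["age_group"].between(0, self.n_age - 1)
        if out_of_range.any():
            raise ValueError(f"age_group indices out of [0, {self.n_age}): "
                             f"{sorted(df.loc[out_of_range, 'age_group'].unique())}")
        dup = df.duplicated(subset=["disease", "country", "age_group"])
        if dup.any():
            offenders = df.loc[dup, ["disease", "country", "age_group"]].head(5)
            raise ValueError(f"duplicate (disease, country, age_group) keys:\n{offenders}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.df["disease"].unique())

    @property
    def countries(self) -> list[str]:
        return sorted(self.df["country"].unique())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


DEFAULT_COLUMN_MAP = {
    "disease": "disease",
    "country": "country",
    "age": "age_group",
    "incidence": "incidence",
}


def read_incidence_csv(path, column_map: dict | None = None,
                       n_age: int = N_AGE_DEFAULT) -> IncidenceTable:
    """Read a delimited incidence table with a configurable column map.

    ``column_map`` maps the roles disease/country/age/incidence to the
    file's header names (so GBD-style exports with e.g. ``cause_name``,
    ``location_name``, ``age_name``, ``val`` columns load unchanged).
    Age values may be band labels ("30-34") or integer indices.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    for role, col in cmap.items():
        if col not in raw.columns:
            raise ValueError(f"column {col!r} (role {role!r}) not in header {list(raw.columns)}")
    df = pd.DataFrame({
        "disease": raw[cmap["disease"]],
        "country": raw[cmap["country"]],
        "age_group": raw[cmap["age"]].map(lambda v: parse_age_label(v, n_age)),
        "incidence": raw[cmap["incidence"]],
    })
    return IncidenceTable(df, n_age=n_age)


def filter_zero_incidence(table: IncidenceTable) -> tuple[IncidenceTable, int]:
    """Drop zero-incidence records; returns (filtered table, removed count).

    Zero cells occur where data is unavailable or the rate is truly
    zero; they are removed before the log transform, and the removed
    count is reported.  Row order is preserved.
    """
    mask = table.df["incidence"] > 0
    removed = int((~mask).sum())
    return IncidenceTable(table.df.loc[mask].reset_index(drop=True), n_age=table.n_age), removed


def log_transform(incidence) -> np.ndarray | float:
    """log10 of a positive incidence rate (per 100,000)."""
    arr = np.asarray(incidence, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("log_transform requires incidence > 0 (filter zeros first)")
    out = np.log10(arr)
    return float(out) if np.isscalar(incidence) else out


def inverse_transform(x) -> tuple:
    """Map a log10 prediction back to (rate per 100,000, proportion).

    The proportion is the per-100,000 rate divided by 100,000, i.e.
    I = 10^x / 100,000.
    """
    arr = np.asarray(x, dtype=float)
    per_100k = np.power(10.0, arr)
    proportion = per_100k / 100_000.0
    if np.isscalar(x):
        return float(per_100k), float(proportion)
    return per_100k, proportion


def encode_age(age_group: int, n_age: int = N_AGE_DEFAULT) -> np.ndarray:
    """One-hot encode an age band index (length n_age, single 1)."""
    if not 0 <= age_group < n_age:
        raise ValueError(f"age_group {age_group} out of range [0, {n_age})")
    vec = np.zeros(n_age)
    vec[age_group] = 1.0
    return vec


@dataclass
class FeatureMatrix:
    """Assembled model inputs: X rows aligned with keys, y in log10 space.

    ``layout`` records segment offsets and provider ids so a trained
    model can verify at predict time that inputs match its features.
    ``applicable`` marks rows a provider could encode (one-hot features
    cannot encode out-of-vocabulary entities).
    """

    X: np.ndarray
    y: np.ndarray
    keys: pd.DataFrame  # disease, country, age_group
    layout: dict = field(default_factory=dict)
    applicable: np.ndarray = None

    def __post_init__(self):
        if self.applicable is None:
            self.applicable = np.ones(len(self.y), dtype=bool)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[idx], y=self.y[idx],
            keys=self.keys.iloc[idx].reset_index(drop=True),
            layout=dict(self.layout), applicable=self.applicable[idx],
        )


def assemble_features(
    table: IncidenceTable,
    disease_provider: Provider,
    country_provider: Provider,
    n_age: int | None = None,
) -> FeatureMatrix:
    """Build x = disease-embedding ‖ country-embedding ‖ age-one-hot per record.

    Targets are log10(incidence); the table must be zero-filtered first.
    Embeddings are computed once per distinct entity and broadcast.
    """
    n_age = n_age or table.n_age
    df = table.df
    if (df["incidence"] <= 0).any():
        raise ValueError("table contains zero incidence; apply filter_zero_incidence first")

    def _embed_all(provider: Provider, names, what: str) -> dict[str, np.ndarray]:
        out = {}
        for name in names:
            try:
                out[name] = provider.embed(name)
            except Exception as exc:
                raise ValueError(f"cannot embed {what} {name!r}: {exc}") from exc
        return out

    d_vecs = _embed_all(disease_provider, df["disease"].unique(), "disease")
    c_vecs = _embed_all(country_provider, df["country"].unique(), "country")
    d_dim = disease_provider.dim
    c_dim = country_provider.dim

    X = np.zeros((len(df), d_dim + c_dim + n_age))
    X[:, :d_dim] = np.vstack([d_vecs[d] for d in df["disease"]])
    X[:, d_dim:d_dim + c_dim] = np.vstack([c_vecs[c] for c in df["country"]])
    X[np.arange(len(df)), d_dim + c_dim + df["age_group"].to_numpy()] = 1.0

    layout = {
        "segments": [
            {"name": "disease", "offset": 0, "dim": d_dim,
             "provider": disease_provider.provider_id},
            {"name": "country", "offset": d_dim, "dim": c_dim,
             "provider": country_provider.provider_id},
            {"name": "age_onehot", "offset": d_dim + c_dim, "dim": n_age, "provider": "onehot"},
        ],
        "total_dim": d_dim + c_dim + n_age,
    }
    return FeatureMatrix(
        X=X, y=log_transform(df["incidence"].to_numpy()),
        keys=df[["disease", "country", "age_group"]].copy(), layout=layout,
    )
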