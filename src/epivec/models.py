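"""Regressors and baselines, trained and applied per split plan.

The primary model is the funnel MLP over embedding features
(:mod:`epivec.mlp`).  Baselines: a per-disease global-average predictor,
a ridge regression on the same embedding features, and MLPs over one-hot
disease/country indicators.  Baselines that cannot encode an entity
unseen in training (the global average for a new disease, one-hot
features for a new disease or country) report not-applicable rather
than guessing; the evaluation layer counts those rows separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge, RidgeCV

from .dataset import FeatureMatrix, IncidenceTable, assemble_features, log_transform
from .embeddings import Provider
from .evaluation import EvaluationReport, evaluate
from .mlp import DEFAULT_HIDDEN_WIDTHS, FunnelMLP
from .splits import SplitPlan

DEFAULT_ALPHA_GRID = tuple(np.logspace(-3, 3, 7))

MODEL_KINDS = ("mlp", "ridge", "global", "onehot-d", "onehot-c", "onehot-dc")


@dataclass
class RegressorConfig:
    """Training configuration for the funnel MLP (and one-hot variants)."""

    hidden_widths: tuple = DEFAULT_HIDDEN_WIDTHS
    learning_rate: float = 3e-4
    batch_size: int = 256
    max_epochs: int = 200
    early_stop_patience: int = 10
    seed: int = 0
    input_standardize: bool = True

    def __post_init__(self):
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_widths"] = list(self.hidden_widths)
        return d


class _Standardizer:
    """Per-feature z-scoring fitted on training rows only."""

    def __init__(self, enabled: bool = True):
        self.enabled = enabled
        self.mean = None
        self.sd = None

    def fit(self, X: np.ndarray) -> "_Standardizer":
        if self.enabled:
            self.mean = X.mean(axis=0)
            sd = X.std(axis=0)
            self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return X
        return (X - self.mean) / self.sd


@dataclass
class TrainedModel:
    """A fitted predictor: pure function of (parameters, input features).

    ``predict`` returns log10-space values, with NaN marking rows the
    model is not applicable to (e.g. an unseen disease for the global
    baseline).
    """

    kind: str
    feature_layout: dict = field(default_factory=dict)
    seed: int = 0
    training_log: object = None
    _impl: object = None
    _scaler: _Standardizer = None
    _table: dict = None  # global baseline lookup

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        if self.kind == "global":
            return self._predict_global(features)
        self._check_layout(features)
        out = np.full(len(features), np.nan)
        ok = features.applicable
        if ok.any():
            X = features.X[ok]
            if self._scaler is not None:
                X = self._scaler.transform(X)
            out[ok] = self._impl.predict(X)
        return out

    def _check_layout(self, features: FeatureMatrix) -> None:
        mine = self.feature_layout.get("segments", [])
        theirs = features.layout.get("segments", [])
        for a, b in zip(mine, theirs):
            if (a["name"], a["dim"], a["provider"]) != (b["name"], b["dim"], b["provider"]):
                raise ValueError(
                    f"feature layout mismatch in segment {a['name']!r}: "
                    f"model has {a}, input has {b}"
                )
        if self.feature_layout.get("total_dim") != features.layout.get("total_dim"):
            raise ValueError("feature layout mismatch: total dimension differs")

    def _predict_global(self, features: FeatureMatrix) -> np.ndarray:
        grouping = self.feature_layout.get("grouping", "disease")
        out = np.full(len(features), np.nan)
        for i, row in enumerate(features.keys.itertuples(index=False)):
            key = row.disease if grouping == "disease" else (row.disease, row.age_group)
            if key in self._table:
                out[i] = self._table[key]
        return out


def build_mlp(input_dim: int, config: RegressorConfig) -> FunnelMLP:
    """Construct the untrained funnel network for a given input width."""
    return FunnelMLP(input_dim, hidden_widths=config.hidden_widths, seed=config.seed)


def train_regressor(model: FunnelMLP, features: FeatureMatrix,
                    config: RegressorConfig) -> TrainedModel:
    """Fit the network on a feature matrix (standardizing on these rows only)."""
    if len(features) == 0:
        raise ValueError("empty feature matrix")
    scaler = _Standardizer(config.input_standardize).fit(features.X)
    log = model.fit(
        scaler.transform(features.X), features.y,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        max_epochs=config.max_epochs, early_stop_patience=config.early_stop_patience,
        seed=config.seed,
    )
    return TrainedModel(kind="mlp", feature_layout=dict(features.layout),
                        seed=config.seed, training_log=log, _impl=model, _scaler=scaler)


def fit_global_baseline(train: IncidenceTable, grouping: str = "disease") -> TrainedModel:
    """Mean log10 incidence per disease (or per disease-age cell).

    A naive reference every model should beat; undefined (not-applicable)
    for diseases absent from training.
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    if grouping not in ("disease", "disease-age"):
        raise ValueError(f"unknown grouping {grouping!r}")
    df = train.df[train.df["incidence"] > 0]
    logy = log_transform(df["incidence"].to_numpy())
    if grouping == "disease":
        keys = df["disease"]
    else:
        keys = list(zip(df["disease"], df["age_group"]))
    means = pd.Series(logy).groupby(pd.Series(list(keys))).mean()
    return TrainedModel(kind="global", feature_layout={"grouping": grouping},
                        _table=means.to_dict())


def fit_ridge(features: FeatureMatrix, alpha_grid=DEFAULT_ALPHA_GRID,
              seed: int = 0) -> TrainedModel:
    """Linear model with L2 penalty; penalty weight by inner 5-fold CV."""
    if len(features) == 0:
        raise ValueError("empty feature matrix")
    alphas = np.asarray(alpha_grid, dtype=float)
    if (alphas <= 0).any():
        raise ValueError("all alphas must be > 0")
    scaler = _Standardizer(True).fit(features.X)
    X = scaler.transform(features.X)
    if len(alphas) > 1:
        impl = RidgeCV(alphas=alphas, cv=5).fit(X, features.y)
    else:
        impl = Ridge(alpha=float(alphas[0]), tol=1e-8).fit(X, features.y)
    return TrainedModel(kind="ridge", feature_layout=dict(features.layout),
                        seed=seed, _impl=impl, _scaler=scaler)


def build_onehot_features(table: IncidenceTable, variant: str,
                          vocab: dict | None = None) -> FeatureMatrix:
    """One-hot disease and/or country indicators concatenated with the age one-hot.

    ``vocab`` (``{"disease": [...], "country": [...]}``) is fixed on the
    training fold; rows whose entity is outside the vocabulary cannot be
    encoded and are marked not-applicable.
    """
    if variant not in ("d", "c", "dc"):
        raise ValueError(f"unknown one-hot variant {variant!r}")
    df = table.df
    if vocab is None:
        vocab = {"disease": table.diseases, "country": table.countries}
    blocks, segments, offset = [], [], 0
    applicable = np.ones(len(df), dtype=bool)
    for role in ("disease", "country"):
        if role[0] not in variant:
            continue
        names = vocab[role]
        index = {name: j for j, name in enumerate(names)}
        block = np.zeros((len(df), len(names)))
        for i, name in enumerate(df[role]):
            j = index.get(name)
            if j is None:
                applicable[i] = False
            else:
                block[i, j] = 1.0
        blocks.append(block)
        segments.append({"name": role, "offset": offset, "dim": len(names),
                         "provider": f"onehot-{role}"})
        offset += len(names)
    age = np.zeros((len(df), table.n_age))
    age[np.arange(len(df)), df["age_group"].to_numpy()] = 1.0
    blocks.append(age)
    segments.append({"name": "age_onehot", "offset": offset, "dim": table.n_age,
                     "provider": "onehot"})
    X = np.hstack(blocks)
    layout = {"segments": segments, "total_dim": X.shape[1], "vocab": vocab,
              "variant": variant}
    return FeatureMatrix(X=X, y=log_transform(df["incidence"].to_numpy()),
                         keys=df[["disease", "country", "age_group"]].copy(),
                         layout=layout, applicable=applicable)


def _table_rows(table: IncidenceTable, idx: np.ndarray) -> IncidenceTable:
    return IncidenceTable(table.df.iloc[idx].reset_index(drop=True), n_age=table.n_age)


def cross_validate(
    table: IncidenceTable,
    plan: SplitPlan,
    model_kind: str = "mlp",
    config: RegressorConfig | None = None,
    disease_provider: Provider | None = None,
    country_provider: Provider | None = None,
    alpha_grid=DEFAULT_ALPHA_GRID,
    global_grouping: str = "disease",
    concordance_group: str = "country",
) -> EvaluationReport:
    """Train per fold on the training rows, predict the validation rows,
    pool validation predictions over folds, and score them.

    All preprocessing (standardization, one-hot vocabularies, inner
    early-stop holdouts) is fitted on each fold's training rows only.
    The table must already be zero-filtered.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")
    config = config or RegressorConfig()
    needs_embeddings = model_kind in ("mlp", "ridge")
    if needs_embeddings and (disease_provider is None or country_provider is None):
        raise ValueError(f"model kind {model_kind!r} requires disease and country providers")

    n = len(table)
    pooled = np.full(n, np.nan)
    truth = log_transform(table.df["incidence"].to_numpy())

    for fold_id, (train_idx, val_idx) in enumerate(plan.folds):
        try:
            train_tab = _table_rows(table, train_idx)
            val_tab = _table_rows(table, val_idx)
            if model_kind == "global":
                model = fit_global_baseline(train_tab, grouping=global_grouping)
                val_feats = build_onehot_features(val_tab, "d")  # keys only
            elif model_kind.startswith("onehot"):
                variant = model_kind.split("-")[1]
                vocab = {"disease": train_tab.diseases, "country": train_tab.countries}
                train_feats = build_onehot_features(train_tab, variant, vocab)
                net = build_mlp(train_feats.X.shape[1], config)
                model = train_regressor(net, train_feats, config)
                model.kind = model_kind
                val_feats = build_onehot_features(val_tab, variant, vocab)
            else:
                train_feats = assemble_features(train_tab, disease_provider, country_provider)
                val_feats = assemble_features(val_tab, disease_provider, country_provider)
                if model_kind == "mlp":
                    net = build_mlp(train_feats.X.shape[1], config)
                    model = train_regressor(net, train_feats, config)
                else:
                    model = fit_ridge(train_feats, alpha_grid=alpha_grid, seed=config.seed)
            pooled[val_idx] = model.predict(val_feats)
        except Exception as exc:
            raise RuntimeError(f"fold {fold_id} failed: {exc}") from exc

    groups = table.df[concordance_group].to_numpy() if concordance_group else None
    strata = table.df["age_group"].to_numpy()
    return evaluate(pooled, truth, group_of=groups, strata=strata)
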