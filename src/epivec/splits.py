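"""Cross-validation split schemes for incidence tables.

Three schemes mirror the three estimation applications:

* ``pair`` — distinct (disease, country) pairs are partitioned across
  folds; all age-group records of a pair travel together, and a
  validation pair never appears in its fold's training set, although its
  disease and country individually may.
* ``country`` — whole countries are held out per fold (prediction for
  previously unseen countries).
* ``disease`` — whole diseases are held out per fold (prediction for
  previously unseen diseases).

Every plan covers each record exactly once across validation folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataset import IncidenceTable


@dataclass
class SplitPlan:
    """k folds of train/validation row indices plus the entities each holds out."""

    scheme: str  # "pair" | "country" | "disease"
    k: int
    seed: int
    folds: list  # list of (train_idx, val_idx) numpy arrays of row positions
    held_out: list  # per fold, the list of held-out entities (pairs or names)

    def __iter__(self):
        return iter(self.folds)

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme, "k": self.k, "seed": self.seed,
            "held_out": [
                [list(e) if isinstance(e, tuple) else e for e in fold]
                for fold in self.held_out
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path, table: IncidenceTable) -> "SplitPlan":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        held_out = [
            [tuple(e) if isinstance(e, list) else e for e in fold]
            for fold in payload["held_out"]
        ]
        folds = _folds_from_entities(table, payload["scheme"], held_out)
        return cls(payload["scheme"], payload["k"], payload["seed"], folds, held_out)


def _entity_keys(table: IncidenceTable, scheme: str):
    df = table.df
    if scheme == "pair":
        return list(zip(df["disease"], df["country"]))
    if scheme == "country":
        return list(df["country"])
    if scheme == "disease":
        return list(df["disease"])
    raise ValueError(f"unknown scheme {scheme!r}")


def _folds_from_entities(table: IncidenceTable, scheme: str, held_out: list):
    keys = _entity_keys(table, scheme)
    fold_of = {}
    for i, fold_entities in enumerate(held_out):
        for e in fold_entities:
            fold_of[e] = i
    row_fold = np.asarray([fold_of[k] for k in keys])
    folds = []
    for i in range(len(held_out)):
        val = np.flatnonzero(row_fold == i)
        train = np.flatnonzero(row_fold != i)
        folds.append((train, val))
    return folds


def _split_entities(table: IncidenceTable, scheme: str, k: int, seed: int,
                    noun: str) -> SplitPlan:
    entities = sorted(set(_entity_keys(table, scheme)))
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(entities) < k:
        raise ValueError(f"only {len(entities)} distinct {noun}s but k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entities))
    held_out = [
        [entities[j] for j in chunk] for chunk in np.array_split(order, k)
    ]
    folds = _folds_from_entities(table, scheme, held_out)
    return SplitPlan(scheme=scheme, k=k, seed=seed, folds=folds, held_out=held_out)


def split_pairs(table: IncidenceTable, k: int, seed: int) -> SplitPlan:
    """Partition distinct (disease, country) pairs into k near-equal folds."""
    return _split_entities(table, "pair", k, seed, "pair")


def split_by_country(table: IncidenceTable, k: int, seed: int) -> SplitPlan:
    """Partition countries into k folds; validation countries are unseen in training."""
    return _split_entities(table, "country", k, seed, "country")


def split_by_disease(table: IncidenceTable, k: int, seed: int) -> SplitPlan:
    """Partition diseases into k folds; validation diseases are unseen in training."""
    return _split_entities(table, "disease", k, seed, "disease")


def single_test_fold(dev_table: IncidenceTable) -> SplitPlan:
    """Independent-test-set evaluation as a one-fold plan: train on everything."""
    n = len(dev_table)
    all_rows = np.arange(n)
    return SplitPlan(scheme="pair", k=1, seed=0, folds=[(all_rows, all_rows)],
                     held_out=[[]])


def validate_split(plan: SplitPlan, table: IncidenceTable) -> dict:
    """Check coverage, disjointness and scheme exclusivity of a plan.

    Returns ``{"passed": bool, "failures": [messages with counter-examples]}``;
    violations are reported, never raised.
    """
    failures: list[str] = []
    n = len(table)
    keys = _entity_keys(table, plan.scheme)

    seen = np.zeros(n, dtype=int)
    for i, (train, val) in enumerate(plan.folds):
        if len(val) == 0:
            failures.append(f"fold {i}: empty validation set")
        if len(train) == 0:
            failures.append(f"fold {i}: empty training set")
        seen[val] += 1
        overlap = np.intersect1d(train, val)
        if overlap.size:
            failures.append(f"fold {i}: rows {overlap[:3].tolist()} in both train and validation")
        if len(train) + len(val) != n:
            failures.append(f"fold {i}: train+validation = {len(train) + len(val)} != {n} rows")
        train_entities = {keys[j] for j in train}
        val_entities = {keys[j] for j in val}
        leaked = train_entities & val_entities
        if leaked:
            failures.append(
                f"fold {i}: validation {plan.scheme} entities leaked into training: "
                f"{sorted(leaked)[:3]}"
            )
    if (seen == 0).any():
        failures.append(f"{int((seen == 0).sum())} rows never validated")
    if (seen > 1).any():
        failures.append(f"{int((seen > 1).sum())} rows validated in more than one fold")
    return {"passed": not failures, "failures": failures}
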