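"""Embedding-context classification experiments.

Before using entity embeddings as regression features, their contextual
information is assessed directly: a linear SVM is trained to predict
disease groups from disease embeddings (and country clusters from
country embeddings).  High held-out accuracy means the embedding
geometry encodes the grouping; chance-level accuracy means it carries
no such context.  Evaluation is repeated stratified 3-fold
cross-validation (10 repeats by default), with the regularization
strength selected by nested search inside each training portion, and
results reported as mean (sd) accuracy over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .embeddings import EmbeddingTable, normalize_name

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class GroupLabeling:
    """A total map from entity names to categorical group labels."""

    entity_labels: dict
    kind: str = "disease-group"  # or "country-cluster"

    def __post_init__(self):
        self.entity_labels = {normalize_name(str(k)): v
                              for k, v in self.entity_labels.items()}

    @property
    def label_set(self) -> list:
        return sorted(set(self.entity_labels.values()))

    def __len__(self) -> int:
        return len(self.entity_labels)


def read_labels(path, kind: str = "disease-group") -> GroupLabeling:
    """Read a two-column delimited file (entity, label).

    Comma- or tab-delimited; an optional header row is skipped.
    Duplicate entities with conflicting labels are an error.
    """
    labels: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sep = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.rstrip("\n").split(sep)]
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 fields, got {len(fields)}")
            entity, label = normalize_name(fields[0]), fields[1]
            if lineno == 1 and entity in ("entity", "name", "disease", "country"):
                continue
            if entity in labels and labels[entity] != label:
                raise ValueError(f"line {lineno}: conflicting labels for {entity!r}: "
                                 f"{labels[entity]!r} vs {label!r}")
            labels[entity] = label
    return GroupLabeling(entity_labels=labels, kind=kind)


def write_labels(labeling: GroupLabeling, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entity, label in labeling.entity_labels.items():
            fh.write(f"{entity},{label}\n")


@dataclass
class ClassificationResult:
    """Mean (sd) held-out accuracy over repeated cross-validation."""

    mean_accuracy: float
    sd_accuracy: float
    per_repeat: list = field(default_factory=list)
    n_entities: int = 0
    n_classes: int = 0
    chance_level: float = 0.0

    def summary(self) -> str:
        return f"{self.mean_accuracy:.2f} ({self.sd_accuracy:.2f})"


def run_classification(
    embeddings: EmbeddingTable,
    labels: GroupLabeling,
    folds: int = 3,
    repeats: int = 10,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> ClassificationResult:
    """Repeated stratified k-fold linear-SVM classification accuracy.

    For each repeat the data is reshuffled with a derived seed and
    scored by stratified ``folds``-fold cross-validation; within each
    training portion the SVM regularization strength is selected from
    ``c_grid`` by a nested stratified search, so no held-out fold
    influences model selection.  Features are standardized per feature
    inside each training portion.  Multi-class handling is one-vs-rest.
    """
    entities = sorted(labels.entity_labels)
    missing = [e for e in entities if e not in embeddings.entries]
    if missing:
        raise ValueError(f"entities without embeddings: {missing[:5]}")
    X = np.vstack([embeddings.entries[e] for e in entities])
    y = np.asarray([labels.entity_labels[e] for e in entities])
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < folds]
    if too_small.size:
        raise ValueError(
            f"classes smaller than fold count {folds}: {too_small.tolist()}")

    accs = []
    for r in range(repeats):
        repeat_seed = (seed * 1_000_003 + r) % (2 ** 31)
        outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=repeat_seed)
        fold_accs = []
        for train_idx, test_idx in outer.split(X, y):
            inner_splits = min(3, int(np.min(np.bincount(
                np.searchsorted(classes, y[train_idx])))))
            pipe = Pipeline([
                ("scale", StandardScaler()),
                ("svm", LinearSVC(max_iter=10_000, random_state=repeat_seed)),
            ])
            if inner_splits >= 2 and len(c_grid) > 1:
                model = GridSearchCV(
                    pipe, {"svm__C": list(c_grid)},
                    cv=StratifiedKFold(n_splits=inner_splits, shuffle=True,
                                       random_state=repeat_seed),
                    n_jobs=None)
            else:
                model = pipe
            model.fit(X[train_idx], y[train_idx])
            fold_accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
        accs.append(float(np.mean(fold_accs)))
    return ClassificationResult(
        mean_accuracy=float(np.mean(accs)), sd_accuracy=float(np.std(accs)),
        per_repeat=accs, n_entities=len(entities), n_classes=len(classes),
        chance_level=float(counts.max() / counts.sum()),
    )
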