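"""Config-driven experiment orchestration.

One YAML config (or an :class:`ExperimentConfig`) describes a full run:
data source (a CSV path or synthetic-world parameters), embedding
providers per entity type, split scheme and fold count, model kind and
training configuration, and the output directory.  A single top-level
seed drives every stage; per-stage seeds are derived as
``crc32("stage-name:seed") mod 2^31`` so an archived config reproduces
the whole run byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import embeddings as emb
from . import synthetic
from .dataset import filter_zero_incidence, read_incidence_csv
from .models import RegressorConfig, cross_validate
from .splits import split_by_country, split_by_disease, split_pairs, validate_split

logger = logging.getLogger(__name__)

_SPLITTERS = {"pair": split_pairs, "country": split_by_country,
              "disease": split_by_disease}


def stage_seed(top_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the experiment seed."""
    return zlib.crc32(f"{stage}:{top_seed}".encode()) % (2 ** 31)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one cross-validated experiment."""

    seed: int = 0
    scheme: str = "pair"
    k: int = 10
    model_kind: str = "mlp"
    out_dir: str | None = None
    # data: either a csv path (+ column map) or synthetic parameters
    data_csv: str | None = None
    column_map: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)  # make_world/sample kwargs
    # providers: {"disease": {...}, "country": {...}}; each spec names a
    # kind (synthetic|hash|word2vec|entity-tsv|fused) and its parameters
    providers: dict = field(default_factory=dict)
    regressor: dict = field(default_factory=dict)
    concordance_group: str = "country"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        return cfg

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate_paths(self) -> None:
        paths = []
        if self.data_csv:
            paths.append(self.data_csv)
        for spec in self.providers.values():
            if isinstance(spec, dict) and spec.get("path"):
                paths.append(spec["path"])
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")


def _build_provider(spec: dict | None, world, entity: str, top_seed: int):
    """Instantiate an embedding provider from its config stanza."""
    spec = spec or {"kind": "synthetic"}
    kind = spec.get("kind", "synthetic")
    if kind == "synthetic":
        if world is None:
            raise ValueError("synthetic provider requires a synthetic data source")
        table = synthetic.derive_embeddings(
            world, entity, dim=spec.get("dim", world.q + 6),
            informativeness=spec.get("informativeness", 1.0),
            seed=stage_seed(top_seed, f"embed-{entity}"))
        return emb.EntityProvider(table=table)
    if kind == "hash":
        return emb.HashProvider(hash_dim=spec.get("dim", 32),
                                seed=stage_seed(top_seed, f"hash-{entity}"))
    if kind == "word2vec":
        table = emb.load_word_vectors(spec["path"], provider_id=spec.get("id", "word2vec"))
        return emb.WordBagProvider(table=table, oov_policy=spec.get("oov_policy", "error"))
    if kind == "entity-tsv":
        table = emb.read_entity_tsv(spec["path"], provider_id=spec.get("id", "entity-tsv"))
        return emb.EntityProvider(table=table)
    if kind == "fused":
        parts = [_build_provider(p, world, entity, top_seed) for p in spec["parts"]]
        return emb.FusedProvider(providers=parts)
    raise ValueError(f"unknown provider kind {kind!r}")


def run_experiment(config: ExperimentConfig):
    """Execute generate/load → filter → split → train → evaluate.

    Returns the :class:`~epivec.evaluation.EvaluationReport`; when
    ``config.out_dir`` is set, also writes the report JSON, the split
    plan JSON, the resolved config, and a JSON-lines log recording every
    stage, seed and row count.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir) if config.out_dir else None
    log_records = []

    def _log(stage: str, **info):
        rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        log_records.append(rec)
        logger.info("%s: %s", stage, info)

    try:
        world = None
        if config.data_csv:
            table = read_incidence_csv(config.data_csv, config.column_map)
            _log("load", rows=len(table), source=config.data_csv)
        else:
            syn = dict(config.synthetic)
            sample_kwargs = {k: syn.pop(k) for k in ("noise_sd", "zero_rate")
                             if k in syn}
            world = synthetic.make_world(seed=stage_seed(config.seed, "world"), **syn)
            table = synthetic.sample_incidence(
                world, seed=stage_seed(config.seed, "sample"), **sample_kwargs)
            _log("generate", rows=len(table), n_diseases=world.n_diseases,
                 n_countries=world.n_countries)

        table, removed = filter_zero_incidence(table)
        _log("filter_zeros", removed=removed, rows=len(table))

        plan = _SPLITTERS[config.scheme](table, config.k,
                                         seed=stage_seed(config.seed, "split"))
        check = validate_split(plan, table)
        if not check["passed"]:
            raise RuntimeError(f"split validation failed: {check['failures']}")
        _log("split", scheme=config.scheme, k=config.k)

        reg = RegressorConfig(seed=stage_seed(config.seed, "train"),
                              **config.regressor)
        d_prov = c_prov = None
        if config.model_kind in ("mlp", "ridge"):
            d_prov = _build_provider(config.providers.get("disease"), world,
                                     "disease", config.seed)
            c_prov = _build_provider(config.providers.get("country"), world,
                                     "country", config.seed)
        report = cross_validate(
            table, plan, model_kind=config.model_kind, config=reg,
            disease_provider=d_prov, country_provider=c_prov,
            concordance_group=config.concordance_group)
        _log("evaluate", mae=report.mae, concordance=report.concordance,
             n_scored=report.n_scored, n_not_applicable=report.n_not_applicable)
    except Exception as exc:
        stage = log_records[-1]["stage"] if log_records else "preflight"
        raise RuntimeError(f"experiment failed after stage {stage!r}: {exc}") from exc

    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        plan.to_json(out_dir / "split_plan.json")
        config.to_yaml(out_dir / "config.yaml")
        with open(out_dir / "log.jsonl", "w", encoding="utf-8") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec) + "\n")
    return report
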