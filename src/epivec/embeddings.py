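"""Entity embeddings: loading, bag-of-words aggregation, fusion, providers.

Disease and country names are treated as short sentences.  Word-level
embedding tables (word2vec/GloVe text format) are aggregated into sentence
embeddings by element-wise min/max/mean over the bag of word vectors;
entity-level tables (precomputed sentence encoders such as BioBERT or USE
exports) are looked up by full normalized name.  Multiple providers can be
fused by concatenation into a single feature vector.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_PUNCT_RE = re.compile(r"[^\w\s]")

#: fixed segment order for bag-of-words aggregation
BAG_SEGMENT_ORDER = ("min", "max", "mean")


class EmbeddingError(ValueError):
    """Raised for format errors, OOV failures, and missing entities."""


def normalize_name(name: str) -> str:
    """Lowercase and trim an entity name (lookup key normalization)."""
    return name.strip().lower()


def tokenize(name: str) -> list[str]:
    """Split an entity name into lowercase word tokens.

    Splits on whitespace, hyphens and slashes; strips remaining
    punctuation; drops empty tokens; preserves order.

    Raises
    ------
    ValueError
        If the name normalizes to zero tokens.
    """
    if not name or not name.strip():
        raise ValueError("empty name cannot be tokenized")
    text = name.lower().replace("-", " ").replace("/", " ")
    text = _PUNCT_RE.sub("", text)
    tokens = text.split()
    if not tokens:
        raise ValueError(f"name {name!r} normalizes to zero tokens")
    return tokens


@dataclass
class EmbeddingTable:
    """A token- or entity-keyed table of fixed-dimension real vectors.

    ``level="word"`` tables are queried token-wise (via
    :func:`embed_bag_of_words`), ``level="entity"`` tables by full
    normalized name (via :func:`embed_entity`).
    """

    entries: dict[str, np.ndarray]
    dim: int
    level: str  # "word" | "entity"
    provider_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.level not in ("word", "entity"):
            raise ValueError(f"level must be 'word' or 'entity', got {self.level!r}")
        for key, vec in self.entries.items():
            if len(vec) != self.dim:
                raise EmbeddingError(
                    f"vector for {key!r} has length {len(vec)}, expected {self.dim}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.entries


@dataclass
class SentenceEmbedding:
    """A single vector for a (possibly multi-word) entity name."""

    vector: np.ndarray
    source_level: str  # "word-aggregated" | "entity-native"
    parts: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.vector)


def load_word_vectors(path, provider_id: str = "word2vec") -> EmbeddingTable:
    """Read a word2vec/GloVe text-format file into a word-level table.

    The format is one token followed by its vector components per line,
    whitespace-separated, with an optional leading ``count dim`` header
    line.  Tokens are normalized to lowercase; on duplicate tokens the
    last occurrence wins (a warning is logged).
    """
    entries: dict[str, np.ndarray] = {}
    dim = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:  # optional "count dim" header
                    int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass
            token, values = parts[0], parts[1:]
            try:
                vec = np.asarray([float(v) for v in values], dtype=float)
            except ValueError as exc:
                raise EmbeddingError(f"line {lineno}: non-numeric value ({exc})") from None
            if dim is None:
                dim = len(vec)
                if dim == 0:
                    raise EmbeddingError(f"line {lineno}: token with no vector components")
            elif len(vec) != dim:
                raise EmbeddingError(
                    f"line {lineno}: vector length {len(vec)} != expected {dim}"
                )
            key = normalize_name(token)
            if key in entries:
                logger.warning("duplicate token %r at line %d; last occurrence wins", key, lineno)
            entries[key] = vec
    if dim is None:
        raise EmbeddingError(f"{path}: empty embedding file")
    return EmbeddingTable(entries=entries, dim=dim, level="word", provider_id=provider_id)


def write_word_vectors(table: EmbeddingTable, path, header: bool = True) -> None:
    """Write a table in word2vec text format (spaces in keys become underscores)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(table.entries)} {table.dim}\n")
        for key, vec in table.entries.items():
            token = key.replace(" ", "_")
            fh.write(token + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def read_entity_tsv(path, provider_id: str = "entity-tsv") -> EmbeddingTable:
    """Read a name→vector TSV (name column followed by float columns)."""
    entries: dict[str, np.ndarray] = {}
    dim = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name, values = fields[0], fields[1:]
            try:
                vec = np.asarray([float(v) for v in values], dtype=float)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise EmbeddingError(f"line {lineno}: non-numeric vector values") from None
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise EmbeddingError(
                    f"line {lineno}: vector length {len(vec)} != expected {dim}"
                )
            entries[normalize_name(name)] = vec
    if dim is None:
        raise EmbeddingError(f"{path}: empty entity table")
    return EmbeddingTable(entries=entries, dim=dim, level="entity", provider_id=provider_id)


def write_entity_tsv(table: EmbeddingTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, vec in table.entries.items():
            fh.write(key + "\t" + "\t".join(f"{v:.8g}" for v in vec) + "\n")


def embed_bag_of_words(
    table: EmbeddingTable, name: str, oov_policy: str = "error"
) -> SentenceEmbedding:
    """Aggregate word vectors of a name into one sentence embedding.

    Over the in-vocabulary token vectors, the element-wise minimum,
    maximum and mean are computed and concatenated in that fixed order,
    giving a vector of length ``3 * table.dim``.

    Parameters
    ----------
    oov_policy
        ``"error"`` aborts if any token is missing, ``"skip"`` drops
        missing tokens, ``"zero"`` substitutes a zero vector.  A name
        whose tokens are *all* out-of-vocabulary is an error under every
        policy.
    """
    if table.level != "word":
        raise ValueError("embed_bag_of_words requires a word-level table")
    if oov_policy not in ("error", "skip", "zero"):
        raise ValueError(f"unknown oov_policy {oov_policy!r}")
    tokens = tokenize(name)
    vectors = []
    n_in_vocab = 0
    for tok in tokens:
        if tok in table.entries:
            vectors.append(table.entries[tok])
            n_in_vocab += 1
        elif oov_policy == "error":
            raise EmbeddingError(f"token {tok!r} of {name!r} is out of vocabulary")
        elif oov_policy == "zero":
            vectors.append(np.zeros(table.dim))
    if n_in_vocab == 0:
        raise EmbeddingError(f"all tokens of {name!r} are out of vocabulary")
    stack = np.vstack(vectors)
    vec = np.concatenate([stack.min(axis=0), stack.max(axis=0), stack.mean(axis=0)])
    return SentenceEmbedding(vector=vec, source_level="word-aggregated", parts=BAG_SEGMENT_ORDER)


def embed_entity(table: EmbeddingTable, name: str) -> SentenceEmbedding:
    """Exact-match lookup of a normalized entity name in an entity-level table."""
    if table.level != "entity":
        raise ValueError("embed_entity requires an entity-level table")
    key = normalize_name(name)
    if key not in table.entries:
        nearest = sorted(table.entries, key=lambda k: (k.split()[0] != key.split()[0], k))[:5]
        raise EmbeddingError(f"entity {name!r} not in table; nearest keys: {nearest}")
    return SentenceEmbedding(vector=table.entries[key].copy(), source_level="entity-native")


def fuse(parts: list[SentenceEmbedding]) -> SentenceEmbedding:
    """Concatenate two or more sentence embeddings in the given order."""
    if len(parts) < 2:
        raise ValueError("fuse requires at least 2 parts")
    vec = np.concatenate([p.vector for p in parts])
    order = tuple(p.source_level for p in parts)
    return SentenceEmbedding(vector=vec, source_level="fused", parts=order)


def hash_embed(name: str, dim: int, seed: int) -> SentenceEmbedding:
    """Deterministic pseudo-random unit-variance vector keyed by (name, seed).

    An uninformative control provider: the same name always maps to the
    same vector, distinct names map to vectors with expected correlation
    zero, so these embeddings carry no context about the entity.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    key = f"{normalize_name(name)}\x00{seed}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return SentenceEmbedding(vector=rng.standard_normal(dim), source_level="hash")


# ---------------------------------------------------------------------------
# Provider abstraction: a uniform name -> vector interface used by the
# feature-assembly layer, hiding whether vectors come from word-level
# aggregation, entity lookup, hashing, or fusion of several providers.
# ---------------------------------------------------------------------------


@dataclass
class Provider:
    """Base embedding provider: maps an entity name to a fixed-length vector."""

    provider_id: str = "base"

    @property
    def dim(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def embed(self, name: str) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class WordBagProvider(Provider):
    """Bag-of-words (min‖max‖mean) provider over a word-level table."""

    table: EmbeddingTable = None
    oov_policy: str = "error"

    def __post_init__(self):
        self.provider_id = self.table.provider_id

    @property
    def dim(self) -> int:
        return 3 * self.table.dim

    def embed(self, name: str) -> np.ndarray:
        return embed_bag_of_words(self.table, name, self.oov_policy).vector


@dataclass
class EntityProvider(Provider):
    """Exact-lookup provider over an entity-level table."""

    table: EmbeddingTable = None

    def __post_init__(self):
        self.provider_id = self.table.provider_id

    @property
    def dim(self) -> int:
        return self.table.dim

    def embed(self, name: str) -> np.ndarray:
        return embed_entity(self.table, name).vector


@dataclass
class HashProvider(Provider):
    """Uninformative deterministic provider (control condition)."""

    hash_dim: int = 32
    seed: int = 0
    provider_id: str = "hash"

    @property
    def dim(self) -> int:
        return self.hash_dim

    def embed(self, name: str) -> np.ndarray:
        return hash_embed(name, self.hash_dim, self.seed).vector


@dataclass
class FusedProvider(Provider):
    """Concatenation of several providers in a fixed, recorded order."""

    providers: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.providers) < 2:
            raise ValueError("FusedProvider requires >= 2 providers")
        self.provider_id = "fused(" + "+".join(p.provider_id for p in self.providers) + ")"

    @property
    def dim(self) -> int:
        return sum(p.dim for p in self.providers)

    def embed(self, name: str) -> np.ndarray:
        return np.concatenate([p.embed(name) for p in self.providers])
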