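"""Molecular and disease-text encoding.

Drugs enter as SMILES strings and leave as fixed-size vectors: an encoder
adapter emits one embedding row per token (up to 512 tokens), and a learned
two-layer tanh attention network scores each token so the pooled drug vector
is a softmax-weighted convex combination of its token embeddings.

Diseases enter as up to three free-text fields (name, synonyms, definition).
Each present field is encoded to a 768-vector, the fields are combined by a
weight-normalized fusion, and the fused vector is projected to 128 dimensions
by a linear map.

Encoder adapters are pluggable.  The package ships a deterministic hashing
adapter (no semantic signal, used for null baselines) and, in
:mod:`ddacl.synthetic`, oracle adapters that embed planted latent factors.
Adapters for pretrained transformers can implement the same two-method
protocol (``encode_tokens`` / ``encode_text``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from ddacl.errors import AdapterError, ConfigurationError, InputError, NumericError

MAX_TOKENS = 512
TOKEN_DIM = 384
TEXT_DIM = 768
DISEASE_PROJ_DIM = 128

DISEASE_FIELDS = ("name", "synonymous", "definition")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    name: str
    synonymous: str = ""
    definition: str = ""

    def present_fields(self) -> dict[str, str]:
        """Non-empty text fields, keyed by canonical field name."""
        out = {}
        for f in DISEASE_FIELDS:
            text = getattr(self, f)
            if text:
                out[f] = text
        return out


@dataclass
class TokenMatrix:
    """Per-drug sequence of token embeddings, one row per token."""

    values: np.ndarray  # (L, d_tok)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise InputError("token matrix must be 2-D with at least one row")
        if self.values.shape[0] > MAX_TOKENS:
            raise InputError(f"token matrix exceeds {MAX_TOKENS} rows")
        if not np.all(np.isfinite(self.values)):
            raise NumericError("token matrix contains non-finite entries")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def d_tok(self) -> int:
        return self.values.shape[1]


@dataclass
class PooledDrugVector:
    values: np.ndarray  # (d_tok,)
    attn_weights: np.ndarray | None = None  # (L,)


@dataclass
class DiseaseVector:
    fused: np.ndarray  # (768,)
    projected: np.ndarray  # (128,)


# ---------------------------------------------------------------------------
# encoder adapters
# ---------------------------------------------------------------------------


@runtime_checkable
class EncoderAdapter(Protocol):
    """Deterministic string -> embedding interface.

    ``encode_tokens`` returns an (L, output_dim) token matrix, L <= 512;
    ``encode_text`` returns the aggregate (first-position) vector for a whole
    text, the analogue of a transformer's [CLS] embedding.
    """

    kind: str
    output_dim: int

    def encode_tokens(self, text: str) -> np.ndarray: ...

    def encode_text(self, text: str) -> np.ndarray: ...


def _digest_seed(key: str) -> int:
    """Stable 63-bit seed from a string (independent of PYTHONHASHSEED)."""
    h = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(h, "big") >> 1


@lru_cache(maxsize=65536)
def _cached_hash_vector(key: str, dim: int) -> np.ndarray:
    rng = np.random.default_rng(_digest_seed(key))
    v = rng.standard_normal(dim)
    v.setflags(write=False)
    return v


def hash_vector(key: str, dim: int) -> np.ndarray:
    """Pseudo-random unit-variance vector stably derived from ``key``."""
    return _cached_hash_vector(key, dim)


class MockHashEncoder:
    """Digest-based encoder with no semantic content.

    Tokenization is character-level; each (character, position) gets a stable
    pseudo-random embedding, so identical strings encode identically and any
    two distinct strings differ.  Supports the one-hot / no-pretrained-model
    ablation tier: downstream models can only memorize entity identity.
    """

    kind = "mock-hash"

    def __init__(self, token_dim: int = TOKEN_DIM, text_dim: int = TEXT_DIM):
        self.output_dim = token_dim
        self.token_dim = token_dim
        self.text_dim = text_dim

    def encode_tokens(self, text: str) -> np.ndarray:
        tokens = list(text)[:MAX_TOKENS]
        if not tokens:
            return np.zeros((1, self.token_dim))
        return np.stack([hash_vector(f"tok|{j}|{t}", self.token_dim) for j, t in enumerate(tokens)])

    def encode_text(self, text: str) -> np.ndarray:
        text = text[: 4 * MAX_TOKENS]  # crude char-budget analogue of 512-token truncation
        if not text:
            return np.zeros(self.text_dim)
        return hash_vector(f"cls|{text}", self.text_dim)


def encode_drug_tokens(record: DrugRecord, enc: EncoderAdapter) -> TokenMatrix:
    """Token-level embedding of a drug's SMILES string, truncated to 512 rows."""
    if not record.smiles:
        raise InputError(f"drug {record.drug_id!r} has an empty SMILES string")
    try:
        values = np.asarray(enc.encode_tokens(record.smiles), dtype=float)
    except Exception as exc:  # adapter failures carry the offending id
        raise AdapterError(f"encoder {enc.kind!r} failed on drug {record.drug_id!r}: {exc}",
                           entity_id=record.drug_id) from exc
    if values.shape[0] > MAX_TOKENS:
        values = values[:MAX_TOKENS]
    return TokenMatrix(values)


def encode_disease_field(text: str, enc: EncoderAdapter) -> np.ndarray:
    """Aggregate representation of one disease text field (zeros for empty text)."""
    return np.asarray(enc.encode_text(text), dtype=float)


# ---------------------------------------------------------------------------
# attention pooling
# ---------------------------------------------------------------------------


@dataclass
class AttentionPoolParams:
    """Parameters of the two-layer tanh scoring network e = W2 tanh(W1 m + b1) + b2."""

    W1: np.ndarray  # (h, d_tok)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (1, h)
    b2: float

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = float(self.b2)
        h, _ = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (1, h):
            raise ConfigurationError("attention parameter shapes are inconsistent")
        for a in (self.W1, self.b1, self.W2):
            if not np.all(np.isfinite(a)):
                raise NumericError("attention parameters contain non-finite entries")

    @classmethod
    def random(cls, d_tok: int = TOKEN_DIM, hidden: int = 128, seed: int = 0) -> "AttentionPoolParams":
        rng = np.random.default_rng(seed)
        return cls(
            W1=rng.standard_normal((hidden, d_tok)) / np.sqrt(d_tok),
            b1=np.zeros(hidden),
            W2=rng.standard_normal((1, hidden)) / np.sqrt(hidden),
            b2=0.0,
        )

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]


def attention_scores(M: TokenMatrix, P: AttentionPoolParams) -> np.ndarray:
    """Per-token scalar scores e_j = W2 tanh(W1 m_j + b1) + b2, row-independent."""
    if P.W1.shape[1] != M.d_tok:
        raise ConfigurationError(
            f"attention W1 expects tokens of width {P.W1.shape[1]}, got {M.d_tok}")
    hidden = np.tanh(M.values @ P.W1.T + P.b1)  # (L, h)
    return (hidden @ P.W2.T).ravel() + P.b2


def softmax_weights(scores: np.ndarray) -> np.ndarray:
    """Stabilized softmax (max subtracted before exponentiation)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise NumericError("attention scores are not finite")
    z = np.exp(scores - scores.max())
    return z / z.sum()


def attention_pool(M: TokenMatrix, P: AttentionPoolParams) -> PooledDrugVector:
    """Softmax-weighted pooling of token rows; weights exported for inspection."""
    alpha = softmax_weights(attention_scores(M, P))
    return PooledDrugVector(values=alpha @ M.values, attn_weights=alpha)


def mean_pool(M: TokenMatrix) -> PooledDrugVector:
    """Uniform-weight pooling — the attention-free ablation."""
    L = M.L
    return PooledDrugVector(values=M.values.mean(axis=0), attn_weights=np.full(L, 1.0 / L))


# ---------------------------------------------------------------------------
# disease fusion and projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldWeights:
    """Relative importance of the name / synonyms / definition fields."""

    w_name: float = 1.0
    w_syn: float = 1.0
    w_def: float = 1.0

    def __post_init__(self):
        ws = (self.w_name, self.w_syn, self.w_def)
        if any(w < 0 for w in ws):
            raise ConfigurationError("field weights must be nonnegative")
        if sum(ws) <= 0:
            raise ConfigurationError("at least one field weight must be positive")

    def as_mapping(self) -> dict[str, float]:
        return {"name": self.w_name, "synonymous": self.w_syn, "definition": self.w_def}


def fuse_fields(vectors: Mapping[str, np.ndarray], weights: FieldWeights) -> np.ndarray:
    """Weight-normalized fusion over the fields present in ``vectors``.

    Missing fields contribute nothing; the weights of present fields are
    renormalized so the output is a convex combination. Scale-invariant in the
    weights.
    """
    if not vectors:
        raise InputError("fusion requires at least one present field")
    wmap = weights.as_mapping()
    total = sum(wmap[f] for f in vectors)
    if total <= 0:
        raise ConfigurationError("all present-field weights are zero")
    out = None
    for f, v in vectors.items():
        term = (wmap[f] / total) * np.asarray(v, dtype=float)
        out = term if out is None else out + term
    return out


@dataclass
class DiseaseProjection:
    """Linear map from fused (768) to compact (128) disease space."""

    matrix: np.ndarray  # (out_dim, in_dim)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ConfigurationError("projection must be a matrix")

    @classmethod
    def random(cls, in_dim: int = TEXT_DIM, out_dim: int = DISEASE_PROJ_DIM,
               seed: int = 0) -> "DiseaseProjection":
        rng = np.random.default_rng(seed)
        return cls(rng.standard_normal((out_dim, in_dim)) / np.sqrt(in_dim))

    @classmethod
    def identity_block(cls, in_dim: int = TEXT_DIM, out_dim: int = DISEASE_PROJ_DIM) -> "DiseaseProjection":
        m = np.zeros((out_dim, in_dim))
        m[:, :out_dim] = np.eye(out_dim)
        return cls(m)


def project_disease(fused: np.ndarray, projection: DiseaseProjection) -> DiseaseVector:
    fused = np.asarray(fused, dtype=float)
    if projection.matrix.shape[1] != fused.shape[0]:
        raise ConfigurationError(
            f"projection expects input of dim {projection.matrix.shape[1]}, got {fused.shape[0]}")
    return DiseaseVector(fused=fused, projected=projection.matrix @ fused)


def encode_disease(record: DiseaseRecord, enc: EncoderAdapter, weights: FieldWeights,
                   projection: DiseaseProjection) -> DiseaseVector:
    """Full disease path: per-field encoding, fusion over present fields, projection."""
    fields = record.present_fields()
    if not fields:
        raise InputError(f"disease {record.disease_id!r} has no non-empty text field")
    vectors = {f: encode_disease_field(t, enc) for f, t in fields.items()}
    return project_disease(fuse_fields(vectors, weights), projection)
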