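"""Synthetic drug-disease benchmark with planted, recoverable signal.

Real curated association tables are sparse bipartite graphs whose structure is
well captured by a low-rank latent-factor model.  The generator draws a latent
vector per drug (u_d) and per disease (v_i) and samples each association
independently with probability sigmoid(u_d . v_i + b), with the bias b solved
by bisection so the expected density matches the target.  Diseases fall into
a small number of latent-space categories (cluster centroids separated well
beyond the encoder noise), mirroring taxonomy labels used for clustering
diagnostics.  Drug strings come from a tiny guaranteed-valid SMILES grammar
(rings of 6, branch depth <= 2, single bonds only) and disease texts from
per-category templates, so the tables look like the real inputs without any
chemistry or clinical realism.

Oracle encoder adapters embed the latent factors (plus Gaussian noise) in the
same shapes a pretrained molecular / text encoder would produce, which makes
the planted signal recoverable end to end; the hashing adapter in
:mod:`ddacl.encoding` provides the matched no-signal null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from ddacl.encoding import (
    TEXT_DIM,
    TOKEN_DIM,
    MAX_TOKENS,
    DiseaseRecord,
    DrugRecord,
    TokenMatrix,
)
from ddacl.errors import AdapterError, ConfigurationError

# linear-chain units that stay valid under plain concatenation
_SMILES_UNITS = (
    "C", "CC", "N", "O", "C(C)", "C(O)", "C(N)", "C(CC)",
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "C(F)", "C(Cl)", "C(C(C)C)",
)

_CATEGORY_TERMS = (
    ("neoplastic", "tumor", "abnormal proliferative growth of tissue"),
    ("cardiovascular", "heart and vessel", "impairment of the circulatory system"),
    ("neurological", "nervous system", "dysfunction of central or peripheral nerves"),
    ("metabolic", "endocrine", "disturbance of biochemical energy pathways"),
    ("infectious", "pathogen borne", "disease caused by microbial invasion"),
    ("immunological", "autoimmune", "disordered immune recognition of self tissue"),
)


@dataclass
class SynthConfig:
    """Shape and signal strength of the generated benchmark.

    The default scale (200 drugs x 150 diseases, density 0.05, latent rank 8,
    encoder noise 0.3, six disease categories) is the reference configuration
    used throughout the test protocol.
    """

    n_drugs: int = 200
    n_diseases: int = 150
    latent_dim: int = 8
    target_density: float = 0.05
    noise_sd: float = 0.3
    n_categories: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_density < 1.0:
            raise ConfigurationError("target_density must lie in (0, 1)")
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        if self.n_categories < 1 or self.noise_sd < 0:
            raise ConfigurationError("invalid category count or noise level")


@dataclass
class SynthDataset:
    config: SynthConfig
    drugs: list[DrugRecord]
    diseases: list[DiseaseRecord]
    positives: list[tuple[str, str]]  # (drug_id, disease_id)
    u: np.ndarray  # (n_drugs, latent_dim)
    v: np.ndarray  # (n_diseases, latent_dim)
    categories: np.ndarray  # (n_diseases,)
    bias: float
    drug_embed: np.ndarray = field(repr=False)  # (TOKEN_DIM, latent_dim)
    disease_embed: np.ndarray = field(repr=False)  # (TEXT_DIM, latent_dim)

    def __post_init__(self):
        self.drug_index = {d.drug_id: k for k, d in enumerate(self.drugs)}
        self.disease_index = {d.disease_id: k for k, d in enumerate(self.diseases)}
        self.smiles_index = {d.smiles: k for k, d in enumerate(self.drugs)}
        self.text_index: dict[str, int] = {}
        for k, d in enumerate(self.diseases):
            for text in (d.name, d.synonymous, d.definition):
                if text:
                    self.text_index[text] = k

    @property
    def density(self) -> float:
        return len(self.positives) / (len(self.drugs) * len(self.diseases))


def _random_smiles(rng: np.random.Generator) -> str:
    n_units = int(rng.integers(3, 11))
    idx = rng.integers(0, len(_SMILES_UNITS), n_units)
    return "".join(_SMILES_UNITS[k] for k in idx)


def _disease_texts(idx: int, cat: int, rng: np.random.Generator) -> tuple[str, str, str]:
    adj, syn_term, def_core = _CATEGORY_TERMS[cat % len(_CATEGORY_TERMS)]
    name = f"{adj} disorder {idx}"
    synonymous = "" if rng.random() < 0.1 else f"{syn_term} syndrome {idx}; {adj} condition type {idx % 9}"
    definition = "" if rng.random() < 0.1 else (
        f"A {adj} disease characterized by {def_core}, catalogued as entry {idx} "
        f"of synthetic class {cat}.")
    return name, synonymous, definition


def generate_benchmark(cfg: SynthConfig) -> SynthDataset:
    """Sample a complete benchmark: entities, texts, latents and associations."""
    rng = np.random.default_rng(cfg.seed)

    # disease categories as latent clusters; centroid separation >= 3 * noise_sd
    centroids = rng.standard_normal((cfg.n_categories, cfg.latent_dim))
    if cfg.n_categories > 1:
        dists = [np.linalg.norm(a - b) for k, a in enumerate(centroids)
                 for b in centroids[k + 1:]]
        floor = 3.0 * cfg.noise_sd
        if min(dists) < floor and min(dists) > 0:
            centroids *= floor / min(dists)
    categories = rng.integers(0, cfg.n_categories, cfg.n_diseases)
    v = centroids[categories] + 0.7 * rng.standard_normal((cfg.n_diseases, cfg.latent_dim))
    u = rng.standard_normal((cfg.n_drugs, cfg.latent_dim))

    # bias solved on the realized score matrix so E[density] hits the target
    G = u @ v.T
    span = float(np.abs(G).max()) + 60.0
    lo, hi = -span, span
    f = lambda b: expit(G + b).mean() - cfg.target_density
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigurationError("cannot bracket the density bias")
    bias = brentq(f, lo, hi, xtol=1e-10)
    P = expit(G + bias)
    adj = rng.random(P.shape) < P

    width = max(len(str(cfg.n_drugs)), len(str(cfg.n_diseases)))
    drugs, seen = [], set()
    for d in range(cfg.n_drugs):
        smiles = _random_smiles(rng)
        while smiles in seen:
            smiles = _random_smiles(rng)
        seen.add(smiles)
        drugs.append(DrugRecord(drug_id=f"DR{d:0{width}d}", smiles=smiles))
    diseases = []
    for i in range(cfg.n_diseases):
        name, syn, definition = _disease_texts(i, int(categories[i]), rng)
        diseases.append(DiseaseRecord(
            disease_id=f"DZ{i:0{width}d}", name=name, synonymous=syn, definition=definition))

    positives = [(drugs[d].drug_id, diseases[i].disease_id)
                 for d, i in zip(*np.nonzero(adj))]

    emb_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0E]))
    drug_embed = emb_rng.standard_normal((TOKEN_DIM, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)
    disease_embed = emb_rng.standard_normal((TEXT_DIM, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)

    return SynthDataset(config=cfg, drugs=drugs, diseases=diseases, positives=positives,
                        u=u, v=v, categories=categories, bias=float(bias),
                        drug_embed=drug_embed, disease_embed=disease_embed)


# ---------------------------------------------------------------------------
# oracle adapters
# ---------------------------------------------------------------------------


def _entity_rng(seed: int, tag: str, key: str) -> np.random.Generator:
    import hashlib
    h = hashlib.blake2b(f"{seed}|{tag}|{key}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(h, "big") >> 1)


class OracleDrugEncoder:
    """Token encoder that embeds each drug's planted latent factor.

    Every token row is the same linear embedding of u_d plus independent
    Gaussian noise, so mean or attention pooling concentrates back onto the
    signal as the token count grows.
    """

    kind = "oracle-latent"

    def __init__(self, dataset: SynthDataset, noise_sd: float | None = None, seed: int = 0):
        self.dataset = dataset
        self.noise_sd = dataset.config.noise_sd if noise_sd is None else noise_sd
        self.seed = seed
        self.output_dim = TOKEN_DIM

    def encode_tokens(self, text: str) -> np.ndarray:
        idx = self.dataset.smiles_index.get(text)
        if idx is None:
            raise AdapterError(f"SMILES not present in the oracle dataset: {text!r}")
        L = min(len(text), MAX_TOKENS)
        base = self.dataset.drug_embed @ self.dataset.u[idx]
        rng = _entity_rng(self.seed, "drug", self.dataset.drugs[idx].drug_id)
        return base + self.noise_sd * rng.standard_normal((L, TOKEN_DIM))

    def encode_text(self, text: str) -> np.ndarray:
        return self.encode_tokens(text).mean(axis=0)


class OracleDiseaseEncoder:
    """Text encoder that embeds the owning disease's latent factor per field."""

    kind = "oracle-latent"

    def __init__(self, dataset: SynthDataset, noise_sd: float | None = None, seed: int = 0):
        self.dataset = dataset
        self.noise_sd = dataset.config.noise_sd if noise_sd is None else noise_sd
        self.seed = seed
        self.output_dim = TEXT_DIM

    def encode_tokens(self, text: str) -> np.ndarray:
        return self.encode_text(text).reshape(1, -1)

    def encode_text(self, text: str) -> np.ndarray:
        if not text:
            return np.zeros(TEXT_DIM)
        idx = self.dataset.text_index.get(text)
        if idx is None:
            raise AdapterError(f"text not present in the oracle dataset: {text[:40]!r}")
        base = self.dataset.disease_embed @ self.dataset.v[idx]
        rng = _entity_rng(self.seed, "disease", text)
        return base + self.noise_sd * rng.standard_normal(TEXT_DIM)


def oracle_drug_encoder(record: DrugRecord, dataset: SynthDataset,
                        noise_sd: float | None = None, seed: int = 0) -> TokenMatrix:
    """Functional form of :class:`OracleDrugEncoder` for a single record."""
    return TokenMatrix(OracleDrugEncoder(dataset, noise_sd, seed).encode_tokens(record.smiles))


def oracle_disease_encoder(record: DiseaseRecord, dataset: SynthDataset,
                           noise_sd: float | None = None, seed: int = 0) -> np.ndarray:
    return OracleDiseaseEncoder(dataset, noise_sd, seed).encode_text(record.name)


def mock_hash_encoder(text: str, token_level: bool = False):
    """Stable digest embedding of a string (tokens or whole-text vector)."""
    from ddacl.encoding import MockHashEncoder
    enc = MockHashEncoder()
    return enc.encode_tokens(text) if token_level else enc.encode_text(text)
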