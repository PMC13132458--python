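"""Experimental protocol: sampling, splits, metrics and diagnostics.

Implements the full evaluation surface around the model:

* balanced negative sampling (unknown pairs, 1:1 with positives);
* stratified 5-fold cross-validation and the C1/C2/C3 cold-start protocols
  (unseen drugs, unseen diseases, both unseen);
* classification metrics (AUROC by the rank/concordance formula with ties
  counted half, AUPR by step interpolation, F1 and accuracy at a threshold);
* per-query ranking metrics (P@K, R@K, MRR, NDCG@10 with binary gains);
* column-relative Gaussian noise injection for robustness experiments;
* embedding-quality diagnostics (cosine separability, Cohen's d, similarity
  AUROC) and clustering agreement (KMeans, NMI/ARI/silhouette);
* the end-to-end cross-validated experiment driver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import (
    accuracy_score,
    adjusted_rand_score,
    average_precision_score,
    f1_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from ddacl import classifier as clf
from ddacl import enhancer as enh
from ddacl.encoding import (
    AttentionPoolParams,
    DiseaseProjection,
    TokenMatrix,
    attention_pool,
    mean_pool,
)
from ddacl.errors import (
    ConfigurationError,
    MetricError,
    SamplingError,
)

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class LabeledPair:
    drug_id: str
    disease_id: str
    label: int

    def key(self) -> Pair:
        return (self.drug_id, self.disease_id)


# ---------------------------------------------------------------------------
# sampling and splits
# ---------------------------------------------------------------------------


def balanced_negatives(positives: Iterable[Pair], drug_ids: Sequence[str],
                       disease_ids: Sequence[str], seed: int = 0) -> list[LabeledPair]:
    """1:1 labeled set: all positives plus an equal number of unknown pairs.

    Negatives are drawn uniformly without replacement from the complement of
    the positive set in the full drug x disease universe.
    """
    pos = list(dict.fromkeys(positives))
    pos_set = set(pos)
    n_universe = len(drug_ids) * len(disease_ids)
    n_unknown = n_universe - len(pos_set)
    if n_unknown < len(pos):
        raise SamplingError(
            f"universe has only {n_unknown} unknown pairs; need {len(pos)} negatives")
    rng = np.random.default_rng(seed)
    # index the universe as drug-major flat positions; sample until quota met
    d_index = {d: k for k, d in enumerate(drug_ids)}
    i_index = {i: k for k, i in enumerate(disease_ids)}
    pos_positions = {d_index[d] * len(disease_ids) + i_index[i] for d, i in pos_set}
    chosen: list[int] = []
    chosen_set: set[int] = set()
    # rejection sampling is fast at realistic densities; fall back to explicit
    # enumeration when the unknown set is small
    if n_unknown <= 4 * len(pos) or n_universe <= 100_000:
        candidates = np.array(sorted(set(range(n_universe)) - pos_positions))
        chosen = rng.choice(candidates, size=len(pos), replace=False).tolist()
    else:
        while len(chosen) < len(pos):
            c = int(rng.integers(0, n_universe))
            if c in pos_positions or c in chosen_set:
                continue
            chosen.append(c)
            chosen_set.add(c)
    out = [LabeledPair(d, i, 1) for d, i in pos]
    for c in chosen:
        out.append(LabeledPair(drug_ids[c // len(disease_ids)],
                               disease_ids[c % len(disease_ids)], 0))
    return out


@dataclass
class SplitSpec:
    """Train/test partition(s) over an indexed list of labeled pairs.

    ``folds`` holds (train_indices, test_indices) tuples: five of them for
    cv5, a single one for the cold-start modes.
    """

    mode: str  # cv5 | C1 | C2 | C3
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    fraction: float = 0.2

    def validate(self, pairs: Sequence[LabeledPair]) -> None:
        n = len(pairs)
        for tr, te in self.folds:
            if set(tr) & set(te):
                raise ConfigurationError("train and test indices overlap")
        if self.mode == "cv5":
            tested = np.concatenate([te for _, te in self.folds])
            if sorted(tested.tolist()) != list(range(n)):
                raise ConfigurationError("cv5 folds must cover every pair exactly once")


def make_cv_folds(pairs: Sequence[LabeledPair], k: int = 5, seed: int = 0) -> SplitSpec:
    """Label-stratified k-fold partition; every pair is tested exactly once."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(pairs) < k:
        raise ConfigurationError("need at least k pairs")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(pairs), dtype=int)
    for label in (0, 1):
        idx = np.array([n for n, p in enumerate(pairs) if p.label == label])
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(idx.size) % k
    folds = []
    all_idx = np.arange(len(pairs))
    for f in range(k):
        te = all_idx[fold_of == f]
        tr = all_idx[fold_of != f]
        folds.append((tr, te))
    return SplitSpec(mode="cv5", folds=folds, seed=seed)


def make_holdout_split(pairs: Sequence[LabeledPair], test_fraction: float = 0.2,
                       seed: int = 0) -> SplitSpec:
    """Single label-stratified train/test split (pair-level, warm-start)."""
    if not 0 < test_fraction < 1:
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    tr, te = [], []
    for label in (0, 1):
        idx = rng.permutation([n for n, p in enumerate(pairs) if p.label == label])
        n_te = max(1, int(round(test_fraction * idx.size)))
        te.extend(idx[:n_te])
        tr.extend(idx[n_te:])
    return SplitSpec(mode="holdout", folds=[(np.array(sorted(tr)), np.array(sorted(te)))],
                     seed=seed, fraction=test_fraction)


def make_coldstart_split(pairs: Sequence[LabeledPair], mode: str, fraction: float = 0.2,
                         seed: int = 0, max_attempts: int = 20) -> SplitSpec:
    """Entity-level holdout: C1 holds out drugs, C2 diseases, C3 both.

    C1: every pair of a sampled drug goes to test, sampled drugs never occur
    in train (mirrored for C2).  C3: test pairs must touch a sampled drug AND
    a sampled disease; pairs touching exactly one sampled entity are dropped
    from both sides, the strictest leak-free reading.
    """
    if mode not in {"C1", "C2", "C3"}:
        raise ConfigurationError(f"unknown cold-start mode {mode!r}")
    drugs = sorted({p.drug_id for p in pairs})
    diseases = sorted({p.disease_id for p in pairs})
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        n_d = max(1, int(round(fraction * len(drugs))))
        n_i = max(1, int(round(fraction * len(diseases))))
        test_drugs = set(rng.choice(drugs, size=n_d, replace=False)) if mode in {"C1", "C3"} else set()
        test_dis = set(rng.choice(diseases, size=n_i, replace=False)) if mode in {"C2", "C3"} else set()
        tr, te = [], []
        for n, p in enumerate(pairs):
            d_hit = p.drug_id in test_drugs
            i_hit = p.disease_id in test_dis
            if mode == "C1":
                (te if d_hit else tr).append(n)
            elif mode == "C2":
                (te if i_hit else tr).append(n)
            else:
                if d_hit and i_hit:
                    te.append(n)
                elif not d_hit and not i_hit:
                    tr.append(n)
                # else: discarded entirely
        te_labels = {pairs[n].label for n in te}
        tr_labels = {pairs[n].label for n in tr}
        if te and tr and te_labels == {0, 1} and tr_labels == {0, 1}:
            if attempt:
                logger.warning("cold-start %s resampled %d time(s) to get a usable split",
                               mode, attempt)
            return SplitSpec(mode=mode, folds=[(np.array(tr), np.array(te))],
                             seed=seed, fraction=fraction)
    raise SamplingError(f"could not build a usable {mode} split in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-formula AUROC: P(random positive outranks random negative), ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUROC requires both classes")
    ranks = rankdata(scores)  # average ranks handle ties at 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under precision-recall via step (average-precision) interpolation."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUPR requires both classes")
    return float(average_precision_score(labels, scores))


@dataclass
class MetricsReport:
    per_fold: list[dict[str, float]] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def summarize(self) -> "MetricsReport":
        if self.per_fold:
            keys = self.per_fold[0].keys()
            self.means = {k: float(np.mean([f[k] for f in self.per_fold])) for k in keys}
        return self

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "means": self.means, "extras": self.extras}


def classification_metrics(scores: np.ndarray, labels: np.ndarray,
                           theta: float) -> dict[str, float]:
    """AUROC/AUPR plus thresholded F1 and accuracy (F1 = 0 when degenerate)."""
    labels = np.asarray(labels, dtype=int)
    pred = clf.binarize(scores, theta)
    return {
        "auroc": auroc(scores, labels),
        "aupr": aupr(scores, labels),
        "f1": float(f1_score(labels, pred, zero_division=0)),
        "accuracy": float(accuracy_score(labels, pred)),
    }


def ranking_metrics(rankings: Mapping[str, tuple[Sequence[str], set[str]]],
                    k_values: Sequence[int] = (1, 3, 5, 10),
                    ndcg_k: int = 10) -> dict[str, float]:
    """Macro-averaged top-K metrics over per-query ordered candidate lists.

    ``rankings`` maps a query id to (candidates ordered best-first, relevant
    set).  Queries without any relevant candidate are excluded with a warning.
    """
    p_at = {k: [] for k in k_values}
    r_at = {k: [] for k in k_values}
    rrs, ndcgs = [], []
    skipped = 0
    for q, (ordered, relevant) in rankings.items():
        rel_in = [c for c in ordered if c in relevant]
        if not rel_in:
            skipped += 1
            continue
        hits = np.array([1.0 if c in relevant else 0.0 for c in ordered])
        n_rel = len(rel_in)
        for k in k_values:
            topk = hits[:k]
            p_at[k].append(topk.sum() / k)
            r_at[k].append(topk.sum() / n_rel)
        first = int(np.argmax(hits)) + 1
        rrs.append(1.0 / first)
        top = hits[:ndcg_k]
        discounts = 1.0 / np.log2(np.arange(2, len(top) + 2))
        dcg = float((top * discounts).sum())
        ideal = min(n_rel, ndcg_k)
        idcg = float((1.0 / np.log2(np.arange(2, ideal + 2))).sum())
        ndcgs.append(dcg / idcg if idcg > 0 else 0.0)
    if skipped:
        logger.warning("ranking_metrics: excluded %d query(ies) with no relevant candidate",
                       skipped)
    if not rrs:
        raise MetricError("no query has a relevant candidate")
    out: dict[str, float] = {"mrr": float(np.mean(rrs)),
                             f"ndcg_at_{ndcg_k}": float(np.mean(ndcgs))}
    for k in k_values:
        out[f"p_at_{k}"] = float(np.mean(p_at[k]))
        out[f"r_at_{k}"] = float(np.mean(r_at[k]))
    return out


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


@dataclass
class NoiseSpec:
    """Column-relative Gaussian corruption: sd = rho * clean-train column sd."""

    rho: float = 0.0
    seed: int = 0
    apply_to: str = "both"  # embeddings | enhanced | both
    phases: str = "both"  # train | test | both

    def __post_init__(self):
        if self.rho < 0:
            raise ConfigurationError("noise level rho must be nonnegative")
        if self.apply_to not in {"embeddings", "enhanced", "both"}:
            raise ConfigurationError(f"unknown apply_to {self.apply_to!r}")
        if self.phases not in {"train", "test", "both"}:
            raise ConfigurationError(f"unknown phases {self.phases!r}")


def inject_noise(features: np.ndarray, spec: NoiseSpec,
                 column_sd: np.ndarray | None = None) -> np.ndarray:
    """Add N(0, (rho * sigma_c)^2) per column; sigma_c from the clean train set.

    Zero-variance columns are left untouched.  With rho = 0 the input is
    returned unchanged (same array values, fresh copy avoided).
    """
    X = np.asarray(features, dtype=float)
    if spec.rho == 0:
        return X
    sd = X.std(axis=0) if column_sd is None else np.asarray(column_sd, dtype=float)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.info("inject_noise: %d zero-variance column(s) left clean", n_const)
    rng = np.random.default_rng(spec.seed)
    return X + rng.standard_normal(X.shape) * (spec.rho * sd)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.info("cosine with a zero vector defined as 0")
        return 0.0
    return float(a @ b / (na * nb))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with the pooled (ddof=1) standard deviation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx + ny < 3:
        return 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    vx = x.var(ddof=1) if nx > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    pooled = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    if pooled == 0:
        return 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / pooled)


@dataclass
class QualityReport:
    mean_pos_sim: float = np.nan
    mean_neg_sim: float = np.nan
    cohens_d: float = np.nan
    sim_auc: float = np.nan
    nmi: float = np.nan
    ari: float = np.nan
    silhouette: float = np.nan

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}


def feature_quality(pos_pairs: Sequence[tuple[int, int]], neg_pairs: Sequence[tuple[int, int]],
                    drug_vecs: np.ndarray, disease_vecs: np.ndarray,
                    n_sample: int = 1000, seed: int = 0) -> QualityReport:
    """Cosine separability of positive vs negative pairs in a shared space."""
    rng = np.random.default_rng(seed)

    def sample(pairs):
        pairs = list(pairs)
        if len(pairs) > n_sample:
            idx = rng.choice(len(pairs), size=n_sample, replace=False)
            pairs = [pairs[k] for k in idx]
        return np.array([_cosine(drug_vecs[d], disease_vecs[i]) for d, i in pairs])

    pos = sample(pos_pairs)
    neg = sample(neg_pairs)
    sims = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return QualityReport(
        mean_pos_sim=float(pos.mean()),
        mean_neg_sim=float(neg.mean()),
        cohens_d=cohens_d(pos, neg),
        sim_auc=auroc(sims, labels),
    )


def clustering_quality(embeddings: np.ndarray, labels: Sequence, k: int = 6,
                       seed: int = 0) -> QualityReport:
    """KMeans agreement with external category labels (NMI, ARI, silhouette)."""
    X = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    if k > X.shape[0]:
        raise ConfigurationError("k exceeds the number of points")
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("need at least two label categories")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    sil = float(silhouette_score(X, assign)) if len(np.unique(assign)) > 1 else 0.0
    return QualityReport(
        nmi=float(normalized_mutual_info_score(labels, assign)),
        ari=float(adjusted_rand_score(labels, assign)),
        silhouette=sil,
    )


# ---------------------------------------------------------------------------
# end-to-end experiment driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything the per-fold pipeline needs beyond the data itself."""

    enhancer: enh.EnhancerConfig = field(default_factory=enh.EnhancerConfig)
    forest: clf.ForestConfig = field(default_factory=clf.ForestConfig)
    attn_hidden: int = 128
    disease_proj_dim: int = 128
    no_cl: bool = False  # ablation: drop the contrastive blocks entirely
    no_att: bool = False  # ablation: mean pooling, no attention training
    train_projection: bool = False  # reserved flag; fixed seeded map by default
    noise: NoiseSpec | None = None
    seed: int = 0


def _pool_all(token_mats: Sequence[TokenMatrix], attn: AttentionPoolParams | None) -> np.ndarray:
    if attn is None:
        return np.stack([mean_pool(m).values for m in token_mats])
    return np.stack([attention_pool(m, attn).values for m in token_mats])


@dataclass
class _Indexed:
    """Entity-indexed view of a dataset's embeddings."""

    drug_ids: list[str]
    dis_ids: list[str]
    d_index: dict[str, int]
    i_index: dict[str, int]
    mats: list[TokenMatrix]
    fused: np.ndarray

    @classmethod
    def build(cls, token_mats: Mapping[str, TokenMatrix],
              fused_disease: Mapping[str, np.ndarray]) -> "_Indexed":
        drug_ids = sorted(token_mats)
        dis_ids = sorted(fused_disease)
        return cls(
            drug_ids=drug_ids, dis_ids=dis_ids,
            d_index={d: k for k, d in enumerate(drug_ids)},
            i_index={i: k for k, i in enumerate(dis_ids)},
            mats=[token_mats[d] for d in drug_ids],
            fused=np.stack([np.asarray(fused_disease[i], dtype=float) for i in dis_ids]),
        )


def _fold_seed(cfg_seed: int, fold_no: int) -> int:
    return int(np.random.default_rng(
        np.random.SeedSequence([cfg_seed, fold_no])).integers(2**31 - 1))


def _feature_stage(pairs: Sequence[LabeledPair], tr: np.ndarray, ix: _Indexed,
                   cfg: PipelineConfig, fold_seed: int):
    """Train the representation stage on the fold's positives.

    Returns (features(idx) -> (X, y), emb_cols): enhanced-feature assembly for
    arbitrary pair indices plus the width of the raw-embedding block.
    """
    proj = DiseaseProjection.random(ix.fused.shape[1], cfg.disease_proj_dim, seed=fold_seed)
    D = ix.fused @ proj.matrix.T

    train_pos = [(ix.d_index[pairs[n].drug_id], ix.i_index[pairs[n].disease_id])
                 for n in tr if pairs[n].label == 1]
    ecfg = enh.EnhancerConfig(**{**cfg.enhancer.__dict__, "seed": fold_seed})
    attn = None if cfg.no_att else AttentionPoolParams.random(
        ix.mats[0].d_tok, cfg.attn_hidden, seed=fold_seed)

    if cfg.no_cl:
        # no contrastive objective => no training signal; keep seeded params
        trained = None
        attn_final = attn
    else:
        Md0 = _pool_all(ix.mats, attn)
        trained = enh.train_enhancer(
            train_pos, Md0, D, ecfg,
            token_matrices=None if cfg.no_att else ix.mats,
            attn_params=attn,
        )
        attn_final = trained.attn_params if not cfg.no_att else None

    Md = _pool_all(ix.mats, attn_final)

    def features(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        di = np.array([ix.d_index[pairs[n].drug_id] for n in idx])
        ii = np.array([ix.i_index[pairs[n].disease_id] for n in idx])
        y = np.array([pairs[n].label for n in idx])
        if cfg.no_cl:
            X = np.concatenate([Md[di], D[ii]], axis=1)
        else:
            X = trained.enhance_batch(Md[di], D[ii])
        return X, y

    return features, Md.shape[1] + D.shape[1]


def _apply_noise(X_tr: np.ndarray, X_te: np.ndarray, noise: NoiseSpec,
                 emb_cols: int, fold_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Phase- and block-aware corruption; sigma from the clean train features."""
    sd = X_tr.std(axis=0)
    col_mask = np.zeros(X_tr.shape[1])
    if noise.apply_to in {"embeddings", "both"}:
        col_mask[:emb_cols] = 1.0
    if noise.apply_to in {"enhanced", "both"}:
        col_mask[:] = 1.0
    eff_sd = sd * col_mask
    if noise.phases in {"train", "both"}:
        X_tr = inject_noise(X_tr, NoiseSpec(noise.rho, fold_seed + 1,
                                            noise.apply_to, noise.phases), column_sd=eff_sd)
    if noise.phases in {"test", "both"}:
        X_te = inject_noise(X_te, NoiseSpec(noise.rho, fold_seed + 2,
                                            noise.apply_to, noise.phases), column_sd=eff_sd)
    return X_tr, X_te


def _score_fold(X_tr, y_tr, X_te, cfg: PipelineConfig, fold_seed: int):
    fcfg = clf.ForestConfig(**{**cfg.forest.__dict__, "seed": fold_seed})
    model = clf.fit_forest(X_tr, y_tr, fcfg)
    theta = clf.youden_threshold(clf.predict_scores(model, X_tr), y_tr).theta_star
    return clf.predict_scores(model, X_te), theta


def run_cv_experiment(
    pairs: Sequence[LabeledPair],
    token_mats: Mapping[str, TokenMatrix],
    fused_disease: Mapping[str, np.ndarray],
    cfg: PipelineConfig,
    split: SplitSpec,
) -> MetricsReport:
    """Train and evaluate the full pipeline on every fold of ``split``.

    Per fold: the contrastive heads (and, unless ablated, the attention
    pooling network) are trained on the fold's positive training pairs only;
    enhanced features are assembled for train and test pairs; the forest is
    fit on the training fold; the Youden threshold is selected on training
    scores; AUROC/AUPR/F1/accuracy are computed on the held-out fold.
    """
    split.validate(pairs)
    ix = _Indexed.build(token_mats, fused_disease)
    report = MetricsReport()
    report.extras["fold_scores"] = []
    for fold_no, (tr, te) in enumerate(split.folds):
        fold_seed = _fold_seed(cfg.seed, fold_no)
        features, emb_cols = _feature_stage(pairs, tr, ix, cfg, fold_seed)
        X_tr, y_tr = features(tr)
        X_te, y_te = features(te)
        if cfg.noise is not None and cfg.noise.rho > 0:
            X_tr, X_te = _apply_noise(X_tr, X_te, cfg.noise, emb_cols, fold_seed)
        scores_te, theta = _score_fold(X_tr, y_tr, X_te, cfg, fold_seed)
        report.per_fold.append(classification_metrics(scores_te, y_te, theta))
        report.extras["fold_scores"].append(
            {"indices": te.tolist(), "scores": scores_te.tolist(),
             "labels": y_te.tolist(), "theta": theta})
    return report.summarize()


def noise_robustness(
    pairs: Sequence[LabeledPair],
    token_mats: Mapping[str, TokenMatrix],
    fused_disease: Mapping[str, np.ndarray],
    cfg: PipelineConfig,
    rhos: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    test_fraction: float = 0.2,
) -> dict[float, dict[str, float]]:
    """Metrics along a noise ladder on one stratified holdout split.

    The representation stage is trained once on the clean training fold; each
    noise level then corrupts the assembled features (train and test phases,
    per ``cfg.noise`` settings) and refits the forest, so the comparison
    across levels is exactly controlled.
    """
    ix = _Indexed.build(token_mats, fused_disease)
    split = make_holdout_split(pairs, test_fraction, seed=cfg.seed)
    tr, te = split.folds[0]
    fold_seed = _fold_seed(cfg.seed, 0)
    features, emb_cols = _feature_stage(pairs, tr, ix, cfg, fold_seed)
    X_tr0, y_tr = features(tr)
    X_te0, y_te = features(te)
    base = cfg.noise or NoiseSpec()
    out = {}
    for rho in rhos:
        spec = NoiseSpec(rho=rho, seed=base.seed, apply_to=base.apply_to, phases=base.phases)
        X_tr, X_te = (X_tr0, X_te0) if rho == 0 else _apply_noise(
            X_tr0, X_te0, spec, emb_cols, fold_seed)
        scores_te, theta = _score_fold(X_tr, y_tr, X_te, cfg, fold_seed)
        out[rho] = classification_metrics(scores_te, y_te, theta)
    return out


def rankings_from_scores(pairs: Sequence[LabeledPair], indices: Sequence[int],
                         scores: Sequence[float], by: str = "drug"):
    """Group scored test pairs into per-query ordered candidate lists.

    ``by='drug'`` ranks candidate diseases per drug; ``by='disease'`` flips
    the direction.  Ties are broken by candidate id for determinism.
    """
    per_query: dict[str, list[tuple[float, str, int]]] = {}
    for n, s in zip(indices, scores):
        p = pairs[n]
        q, c = (p.drug_id, p.disease_id) if by == "drug" else (p.disease_id, p.drug_id)
        per_query.setdefault(q, []).append((float(s), c, p.label))
    rankings = {}
    for q, items in per_query.items():
        items.sort(key=lambda t: (-t[0], t[1]))
        ordered = [c for _, c, _ in items]
        relevant = {c for _, c, lab in items if lab == 1}
        rankings[q] = (ordered, relevant)
    return rankings
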