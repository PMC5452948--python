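"""Genetic-algorithm selection of informative feature subsets.

Each individual carries a bit mask ("chromosome") over the candidate features;
fitness is the Fscore of the *any-feature* prediction rule: a promoter is
predicted positive iff it contains at least one of the masked-in features.
The population size equals the number of training promoters; evolution uses
tournament selection (k=2), uniform crossover, per-bit mutation (p=0.05) and
one elite. Three stopping rules: a generation budget (default 10,000), a
fitness target (Fscore ≥ 0.8), and an early stop triggered when more than half
of the positive training promoters score higher than 90% of the controls under
the KL-weighted score restricted to the masked-in features.

Model selection is fivefold cross-validation: the GA trains on four folds, the
best chromosome is measured on the held-out fold, and the consensus model is
the set of features present in at least four of the five fold-best masks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import BinaryFeatureMatrix, FeatureDescriptor
from .scoring import FeatureWeight, compute_weights, feature_weight_vector


@dataclass
class Chromosome:
    mask: np.ndarray  # bool vector over the candidate features
    fitness: float | None = None

    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class GAConfig:
    mutation_prob: float = 0.05
    max_iters: int = 10_000
    fscore_stop: float = 0.8
    early_stop_pos_fraction: float = 0.5
    early_stop_neg_quantile: float = 0.9
    seed: int = 0
    selection: str = "tournament_k2"  # or "roulette"
    elitism: int = 1
    init_q: float = 0.1  # Bernoulli rate of the initial bit masks

    def __post_init__(self):
        for p in (self.mutation_prob, self.early_stop_pos_fraction,
                  self.early_stop_neg_quantile, self.init_q):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.selection not in ("tournament_k2", "roulette"):
            raise ValueError(f"unknown selection operator {self.selection!r}")


@dataclass
class EvolveResult:
    best: Chromosome
    log: list  # (generation, best_fitness, mean_fitness)
    stop_reason: str  # {max_iters, fscore_stop, early_stop}


@dataclass
class ModelResult:
    """Cross-validated model: per-fold best chromosomes, their test Fscores,
    the ≥4-of-5 consensus features and their weights."""

    fold_best: list[Chromosome]
    fold_fscores: list[float]
    overall_fscore: float
    consensus_features: list[FeatureDescriptor]
    weights: list[FeatureWeight]
    fold_confusions: list[tuple]  # (tp, fp, fn, tn) on the test fold
    candidate_features: list[FeatureDescriptor] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def fscore(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, Fscore) with the 0-denominator convention of 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def confusion(mask: np.ndarray, values: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    """Any-feature confusion counts: positives with ≥1 masked-in feature are TP,
    without any are FN; controls with ≥1 are FP, without any TN."""
    pred = values[:, mask].any(axis=1) if mask.any() else np.zeros(len(labels), bool)
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return tp, fp, fn, tn


def evaluate_chromosome(ch: Chromosome | np.ndarray, values: np.ndarray,
                        labels: np.ndarray) -> float:
    mask = ch.mask if isinstance(ch, Chromosome) else np.asarray(ch, dtype=bool)
    tp, fp, fn, _ = confusion(mask, values, labels)
    return fscore(tp, fp, fn)[2]


def _population_fitness(masks: np.ndarray, values: np.ndarray,
                        labels: np.ndarray) -> np.ndarray:
    hits = (values.astype(np.uint16) @ masks.T.astype(np.uint16)) > 0  # genes x pop
    pos = labels == 1
    tp = hits[pos].sum(axis=0).astype(float)
    fp = hits[~pos].sum(axis=0).astype(float)
    fn = pos.sum() - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, 2 * tp / denom, 0.0)  # == 2PR/(P+R)


def _best_index(masks: np.ndarray, fits: np.ndarray) -> int:
    """Highest fitness; ties prefer fewer selected features, then lexicographically
    smaller mask (parsimony matches the goal of small informative sets)."""
    best = fits.max()
    cand = np.nonzero(fits >= best - 1e-12)[0]
    if len(cand) == 1:
        return int(cand[0])
    sizes = masks[cand].sum(axis=1)
    cand = cand[sizes == sizes.min()]
    if len(cand) == 1:
        return int(cand[0])
    order = np.lexsort(masks[cand].astype(np.uint8).T[::-1])
    return int(cand[order[0]])


def _beats(mask_a: np.ndarray, fit_a: float, mask_b: np.ndarray | None, fit_b: float) -> bool:
    if mask_b is None or fit_a > fit_b + 1e-12:
        return True
    if fit_a < fit_b - 1e-12:
        return False
    na, nb = mask_a.sum(), mask_b.sum()
    if na != nb:
        return na < nb
    return tuple(mask_a.astype(np.uint8)) < tuple(mask_b.astype(np.uint8))


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def evolve(values: np.ndarray, labels: np.ndarray, config: GAConfig) -> EvolveResult:
    """Run the GA on one training matrix; deterministic given ``config.seed``.

    The population size equals the number of training promoters. The early-stop
    score uses KL weights computed once from the training matrix; within the GA
    the binarized matrix is the data, so occurrence counts reduce to presence
    indicators there.
    """
    values = np.asarray(values, dtype=np.uint8)
    labels = np.asarray(labels)
    n, n_feat = values.shape
    if n_feat == 0:
        raise ValueError("no candidate features")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(config.seed)
    pop = n
    masks = rng.random((pop, n_feat)) < config.init_q
    w_all = feature_weight_vector(values, labels)
    pos = labels == 1
    best_mask, best_fit = None, -1.0
    log: list[tuple] = []
    stop = "max_iters"
    for gen in range(config.max_iters):
        fits = _population_fitness(masks, values, labels)
        gi = _best_index(masks, fits)
        if _beats(masks[gi], fits[gi], best_mask, best_fit):
            best_mask, best_fit = masks[gi].copy(), float(fits[gi])
        log.append((gen, float(fits[gi]), float(fits.mean())))
        if best_fit >= config.fscore_stop:
            stop = "fscore_stop"
            break
        if _early_stop(best_mask, values, labels, pos, w_all, config):
            stop = "early_stop"
            break
        masks = _next_generation(masks, fits, rng, config, best_mask)
    return EvolveResult(best=Chromosome(mask=best_mask, fitness=best_fit),
                        log=log, stop_reason=stop)


def _early_stop(mask, values, labels, pos, w_all, config) -> bool:
    if mask is None or not mask.any():
        return False
    scores = values @ (w_all * mask)
    pos_scores, neg_scores = scores[pos], scores[~pos]
    if len(neg_scores) == 0:
        return False
    beaten = (pos_scores[:, None] > neg_scores[None, :]).mean(axis=1)
    frac = float(np.mean(beaten >= config.early_stop_neg_quantile))
    return frac > config.early_stop_pos_fraction


def _next_generation(masks, fits, rng, config, best_mask):
    pop, n_feat = masks.shape
    if config.selection == "tournament_k2":
        a = rng.integers(0, pop, size=pop)
        b = rng.integers(0, pop, size=pop)
        winners = np.where(fits[a] >= fits[b], a, b)
    else:  # roulette
        tot = fits.sum()
        p = fits / tot if tot > 0 else np.full(pop, 1.0 / pop)
        winners = rng.choice(pop, size=pop, p=p)
    parents = masks[winners]
    pairs = rng.permutation(pop)
    children = parents.copy()
    for k in range(0, pop - 1, 2):
        i, j = pairs[k], pairs[k + 1]
        swap = rng.random(n_feat) < 0.5  # uniform crossover
        children[i] = np.where(swap, parents[j], parents[i])
        children[j] = np.where(swap, parents[i], parents[j])
    flip = rng.random(children.shape) < config.mutation_prob
    children ^= flip
    if config.elitism > 0 and best_mask is not None:
        children[0] = best_mask
    return children


# ---------------------------------------------------------------------------
# Cross-validation and consensus
# ---------------------------------------------------------------------------

def _stratified_folds(labels: np.ndarray, k: int, rng) -> list[np.ndarray]:
    folds = [[] for _ in range(k)]
    for cls in (1, 0):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        for i, g in enumerate(idx):
            folds[i % k].append(g)
    return [np.sort(np.array(f)) for f in folds]


def cross_validate(matrix: BinaryFeatureMatrix, config: GAConfig, k: int = 5,
                   weight_matrix: BinaryFeatureMatrix | None = None,
                   consensus_min: int | None = None) -> ModelResult:
    """Fivefold CV: evolve on 4 folds, measure the best chromosome on the held-out
    fold; overall Fscore is the mean of the five test Fscores; the consensus
    model keeps features present in ≥4 of the 5 fold-best masks. Consensus
    weights come from ``weight_matrix`` (the feature-computation cohort) when
    given, else from ``matrix``.
    """
    labels = matrix.labels
    for cls in (0, 1):
        if int(np.sum(labels == cls)) < k:
            raise ValueError(f"class {cls} has fewer than {k} members")
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(labels, k, rng)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(config.seed).spawn(k)]
    fold_best: list[Chromosome] = []
    fold_fscores: list[float] = []
    fold_confusions: list[tuple] = []
    for f in range(k):
        test_idx = folds[f]
        train_idx = np.sort(np.concatenate([folds[j] for j in range(k) if j != f]))
        cfg = GAConfig(**{**config.__dict__, "seed": fold_seeds[f]})
        res = evolve(matrix.values[train_idx], labels[train_idx], cfg)
        fold_best.append(res.best)
        tp, fp, fn, tn = confusion(res.best.mask, matrix.values[test_idx], labels[test_idx])
        fold_fscores.append(fscore(tp, fp, fn)[2])
        fold_confusions.append((tp, fp, fn, tn))
    min_votes = consensus_min if consensus_min is not None else max(k - 1, 1)
    votes = np.sum([ch.mask for ch in fold_best], axis=0)
    consensus = [matrix.features[i] for i in np.nonzero(votes >= min_votes)[0]]
    wm = weight_matrix if weight_matrix is not None else matrix
    weights = compute_weights(wm, consensus)
    return ModelResult(fold_best=fold_best, fold_fscores=fold_fscores,
                       overall_fscore=float(np.mean(fold_fscores)),
                       consensus_features=consensus, weights=weights,
                       fold_confusions=fold_confusions,
                       candidate_features=list(matrix.features))
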