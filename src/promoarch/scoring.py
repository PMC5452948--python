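"""Kullback–Leibler feature weights and weighted occurrence-count promoter scores.

A feature's weight is the expected KL divergence of the class distribution
given the feature's value, normalized by the entropy of the feature's value
distribution:

    w_i = [ Σ_j P(o_ij) · D_KL(C | o_ij) ] / [ −Σ_j P(o_ij) · log P(o_ij) ]
    D_KL(C | o_ij) = Σ_c P(c | o_ij) · log( P(c | o_ij) / P(c) )

with j ranging over the observed values (present/absent) of feature i.
Weights are deliberately *not* renormalized to sum to one across features, so
rare but highly class-informative features keep large weights. A promoter's
score is Σ_i w_i · n_i where n_i counts the feature's qualifying
instantiations (occurrences, or occurrence pairs for pair features).

Natural log is used internally; the weight is a ratio of same-base sums and is
therefore base-independent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import (BinaryFeatureMatrix, FeatureConfig, FeatureDescriptor,
                       count_feature)

MODEL_SCHEMA_VERSION = 1


@dataclass
class FeatureWeight:
    """One feature's weight with the per-value frequencies and KL terms behind it."""

    feature: FeatureDescriptor
    w: float
    p_o: dict  # value -> P(o_ij)
    kl: dict  # value -> D_KL(C | o_ij)
    constant: bool = False  # column had a single value; w set to 0


@dataclass
class PromoterScore:
    gene_id: str
    score: float
    counts: dict  # feature string -> n_i


def _column(matrix: BinaryFeatureMatrix, feature: FeatureDescriptor) -> np.ndarray:
    try:
        idx = [str(f) for f in matrix.features].index(str(feature))
    except ValueError:
        raise KeyError(f"feature {feature} not in matrix") from None
    return matrix.values[:, idx]


def kl_divergence_for_value(matrix: BinaryFeatureMatrix, feature: FeatureDescriptor,
                            value: int) -> float:
    """D_KL(C | o_ij) for one value j of a feature, with class priors estimated
    from the matrix labels (maximum likelihood, no smoothing)."""
    col = _column(matrix, feature)
    labels = matrix.labels
    if labels.min() == labels.max():
        raise ValueError("matrix must contain both classes")
    sel = col == value
    if not sel.any():
        raise ValueError(f"value {value} absent from the feature column")
    kl = 0.0
    n = len(labels)
    for c in (0, 1):
        prior = float(np.mean(labels == c))
        cond = float(np.mean(labels[sel] == c))
        if cond > 0:
            kl += cond * np.log(cond / prior)
    return float(kl)


def feature_weight(matrix: BinaryFeatureMatrix, feature: FeatureDescriptor) -> FeatureWeight:
    """Weight of one feature from the matrix; constant columns get w = 0, flagged."""
    col = _column(matrix, feature)
    values = sorted(set(col.tolist()))
    p_o = {j: float(np.mean(col == j)) for j in values}
    if len(values) < 2:
        return FeatureWeight(feature=feature, w=0.0, p_o=p_o,
                             kl={j: 0.0 for j in values}, constant=True)
    kl = {j: kl_divergence_for_value(matrix, feature, j) for j in values}
    num = sum(p_o[j] * kl[j] for j in values)
    den = -sum(p_o[j] * np.log(p_o[j]) for j in values)
    return FeatureWeight(feature=feature, w=float(num / den), p_o=p_o, kl=kl)


def compute_weights(matrix: BinaryFeatureMatrix,
                    features: Sequence[FeatureDescriptor] | None = None) -> list[FeatureWeight]:
    feats = matrix.features if features is None else features
    return [feature_weight(matrix, f) for f in feats]


def feature_weight_vector(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized per-column weights for a binary matrix (used inside the GA's
    early-stop score); constant columns get 0."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n, F = values.shape
    out = np.zeros(F)
    p1 = values.mean(axis=0)
    priors = np.array([np.mean(labels == 0), np.mean(labels == 1)])
    for j, sel_val in ((1, values == 1), (0, values == 0)):
        cnt = sel_val.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond1 = (sel_val * (labels == 1)[:, None]).sum(axis=0) / np.maximum(cnt, 1)
        kl = np.zeros(F)
        for c, prior in ((0, priors[0]), (1, priors[1])):
            cond = cond1 if c == 1 else 1.0 - cond1
            with np.errstate(invalid="ignore", divide="ignore"):
                term = np.where(cond > 0, cond * np.log(np.maximum(cond, 1e-300) / prior), 0.0)
            kl += term
        pj = p1 if j == 1 else 1.0 - p1
        out += np.where(cnt > 0, pj * kl, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ent = -(np.where(p1 > 0, p1 * np.log(np.maximum(p1, 1e-300)), 0.0)
                + np.where(p1 < 1, (1 - p1) * np.log(np.maximum(1 - p1, 1e-300)), 0.0))
        out = np.where(ent > 0, out / np.maximum(ent, 1e-300), 0.0)
    return out


def score_region(weights: Sequence[FeatureWeight], occs,
                 gene_id: str = "", config: FeatureConfig | None = None) -> PromoterScore:
    """score = Σ_i w_i · n_i over the model's features for one promoter's occurrences."""
    counts = {}
    total = 0.0
    for fw in weights:
        n_i = count_feature(fw.feature, occs, config)
        counts[str(fw.feature)] = n_i
        total += fw.w * n_i
    gid = gene_id or (occs[0].gene_id if occs else "")
    return PromoterScore(gene_id=gid, score=float(total), counts=counts)


# ---------------------------------------------------------------------------
# Trained-model artifact
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """The trained artifact: consensus features, their weights and the scan/window
    configuration needed to apply them to new promoters."""

    features: list[FeatureDescriptor]
    weights: list[float]
    motif_names: list[str]
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    threshold_fraction: float = 0.8
    overall_fscore: float | None = None
    version: int = MODEL_SCHEMA_VERSION

    def feature_weights(self) -> list[FeatureWeight]:
        return [FeatureWeight(feature=f, w=w, p_o={}, kl={})
                for f, w in zip(self.features, self.weights)]

    def score(self, occs, gene_id: str = "") -> PromoterScore:
        return score_region(self.feature_weights(), occs, gene_id, self.feature_config)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "features": [str(f) for f in self.features],
            "weights": [float(w) for w in self.weights],
            "motif_names": list(self.motif_names),
            "feature_config": self.feature_config.to_dict(),
            "threshold_fraction": self.threshold_fraction,
            "overall_fscore": self.overall_fscore,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "Model":
        with open(path) as fh:
            d = json.load(fh)
        if d["version"] != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {d['version']}")
        return cls(features=[FeatureDescriptor.parse(s) for s in d["features"]],
                   weights=list(d["weights"]), motif_names=list(d["motif_names"]),
                   feature_config=FeatureConfig.from_dict(d["feature_config"]),
                   threshold_fraction=d["threshold_fraction"],
                   overall_fscore=d.get("overall_fscore"))
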