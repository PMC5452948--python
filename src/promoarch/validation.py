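"""Model validation: genome-wide ranking, hypergeometric enrichment of the top
genes against an expressed set, Benjamini–Hochberg FDR, label-shuffle Fscore
significance, and strict-containment overlap of motif hits with annotated
regions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import BinaryFeatureMatrix
from .ga import confusion, fscore
from .motifs import MotifOccurrence
from .promoters import PromoterRecord
from .scoring import FeatureWeight, score_region


@dataclass
class EnrichmentResult:
    """Overlap of the top-scoring genes with an expressed-gene set."""

    n_top: int
    count: int
    expressed_fraction: float
    pvalue: float
    fdr: float | None = None

    def to_dict(self) -> dict:
        return {"n_top": self.n_top, "count": self.count,
                "expressed_fraction": self.expressed_fraction,
                "pvalue": self.pvalue, "fdr": self.fdr}


def rank_genome(weights: Sequence[FeatureWeight], occurrence_index: dict,
                exclude: Iterable[str] = (), n_top: int = 100,
                config=None) -> pd.DataFrame:
    """Score every non-excluded promoter and rank by descending score.

    Ties are broken by gene id (lexicographic) for reproducibility. Returns a
    DataFrame with gene_id, score, rank (1-based) and a top-``n_top`` flag.
    """
    excluded = set(exclude)
    genes = [g for g in occurrence_index if g not in excluded]
    if n_top > len(genes):
        raise ValueError(f"n_top={n_top} exceeds the {len(genes)}-promoter universe")
    rows = [(g, score_region(weights, occurrence_index[g], g, config).score)
            for g in genes]
    df = pd.DataFrame(rows, columns=["gene_id", "score"])
    df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["top"] = df["rank"] <= n_top
    return df


def hypergeometric_enrichment(count: int, n_top: int, n_expressed: int,
                              n_universe: int) -> float:
    """Upper-tail P(X ≥ count) for drawing ``n_top`` genes from a universe with
    ``n_expressed`` successes."""
    if not (0 <= count <= min(n_top, n_expressed)):
        raise ValueError("count must be <= min(n_top, n_expressed)")
    if n_expressed > n_universe or n_top > n_universe:
        raise ValueError("expressed set and draw must fit inside the universe")
    return float(stats.hypergeom.sf(count - 1, n_universe, n_expressed, n_top))


def enrichment_of_top(ranked: pd.DataFrame, expressed_ids: Iterable[str],
                      n_top: int = 100) -> EnrichmentResult:
    """Hypergeometric enrichment of the expressed genes among the top-``n_top``
    ranked genes; the universe is every ranked gene."""
    expressed = set(expressed_ids) & set(ranked["gene_id"])
    top = ranked.loc[ranked["rank"] <= n_top, "gene_id"]
    count = int(top.isin(expressed).sum())
    p = hypergeometric_enrichment(count, n_top, len(expressed), len(ranked))
    return EnrichmentResult(n_top=n_top, count=count,
                            expressed_fraction=len(expressed) / len(ranked),
                            pvalue=p)


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (the classic `p.adjust(method="fdr")`)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def fscore_permutation_pvalue(matrix: BinaryFeatureMatrix, mask, n_perm: int = 10_000,
                              seed: int = 0) -> float:
    """Label-shuffle significance of a feature set's Fscore.

    Class labels are shuffled ``n_perm`` times, the any-feature Fscore is
    recomputed each time, and p = (# shuffled Fscores strictly greater than the
    observed one) / n_perm. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    mask = np.asarray(mask, dtype=bool)
    pred = matrix.values[:, mask].any(axis=1).astype(np.int64)
    labels = matrix.labels.astype(np.int64)
    npos = int(labels.sum())
    npred = int(pred.sum())
    obs_tp = int(pred @ labels)
    # F = 2TP/(2TP+FP+FN) and FP+FN = npred+npos-2TP, so F = 2TP/(npred+npos)
    denom = npred + npos
    obs_f = 2 * obs_tp / denom if denom else 0.0
    rng = np.random.default_rng(seed)
    greater = 0
    for _ in range(n_perm):
        tp = int(pred @ rng.permutation(labels))
        f = 2 * tp / denom if denom else 0.0
        if f > obs_f:
            greater += 1
    return greater / n_perm


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Gene-level Fscore, accuracy, sensitivity (= recall) and specificity."""
    precision, recall, f = fscore(tp, fp, fn)
    total = tp + fp + fn + tn
    return {"fscore": f, "precision": precision, "sensitivity": recall,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
            "accuracy": (tp + tn) / total if total else 0.0}


# ---------------------------------------------------------------------------
# Genomic overlap
# ---------------------------------------------------------------------------

def map_occurrence_to_genomic(occ: MotifOccurrence,
                              promoter: PromoterRecord) -> tuple[str, int, int, str]:
    """Convert a promoter-relative occurrence to (chrom, start, end, genomic strand)."""
    if promoter.strand == "+":
        g0 = promoter.genomic_coord(occ.start)
        return promoter.chrom, g0, g0 + (occ.end - occ.start), occ.strand
    g_hi = promoter.genomic_coord(occ.start)  # highest genomic coordinate of the match
    g_lo = promoter.genomic_coord(occ.end - 1)
    strand = "-" if occ.strand == "+" else "+"
    return promoter.chrom, g_lo, g_hi + 1, strand


def overlap_with_intervals(occurrences, intervals) -> list:
    """Keep exactly the occurrences lying *entirely* inside some interval.

    ``occurrences``: (chrom, start, end, ...) tuples or objects with those
    attributes; ``intervals``: (chrom, start, end) tuples. Strand is ignored;
    partial overlaps are dropped.
    """
    def _fields(x):
        if hasattr(x, "chrom"):
            return x.chrom, x.start, x.end
        return x[0], x[1], x[2]

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        c, s, e = _fields(iv)
        by_chrom.setdefault(c, []).append((s, e))
    chrom_names = set(by_chrom)
    arr = {c: (np.array([s for s, _ in sorted(v)]), np.array([e for _, e in sorted(v)]))
           for c, v in by_chrom.items()}
    kept = []
    warned = False
    for occ in occurrences:
        c, s, e = _fields(occ)
        if c not in arr:
            if not warned and chrom_names and any(
                    c.removeprefix("chr") == k.removeprefix("chr") for k in chrom_names):
                warnings.warn("mixed chromosome naming between occurrences and intervals")
                warned = True
            continue
        starts, ends = arr[c]
        if bool(np.any((starts <= s) & (e <= ends))):
            kept.append(occ)
    return kept
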