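"""Promoter extraction, near-duplicate pruning and gene-set splitting.

A promoter is the window from 1,500 bp upstream to 500 bp downstream of the
transcription start site (TSS), stored in *gene orientation*: index 0 is the
most upstream base (−1500 relative to the TSS) and index 1999 is +499.
Coordinates are 0-based, half-open throughout; promoter index ``p`` maps to the
TSS-relative coordinate ``r = p − 1500``.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneRow

UPSTREAM = 1500
DOWNSTREAM = 500
PROMOTER_LEN = UPSTREAM + DOWNSTREAM

_RC = str.maketrans("ACGTNacgtn", "TGCANTGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class PromoterError(ValueError):
    pass


@dataclass
class PromoterRecord:
    """One gene's promoter sequence in gene orientation with TSS-anchored coordinates."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    seq: str
    offset_of_tss: int = UPSTREAM
    truncated: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise PromoterError(f"{self.gene_id}: malformed strand {self.strand!r}")

    def tss_relative(self, p: int) -> int:
        """TSS-relative coordinate of promoter index ``p``."""
        return p - self.offset_of_tss

    def genomic_coord(self, p: int) -> int:
        """Genomic coordinate of the base at promoter index ``p``."""
        r = self.tss_relative(p)
        return self.tss + r if self.strand == "+" else self.tss - r


def extract_promoters(genome: Mapping[str, str], genes: Iterable[GeneRow],
                      upstream: int = UPSTREAM, downstream: int = DOWNSTREAM,
                      strict: bool = True) -> list[PromoterRecord]:
    """Extract TSS-anchored promoters ([TSS−upstream, TSS+downstream) in gene orientation).

    Minus-strand promoters are reverse-complemented so every record reads
    upstream → downstream. Windows running off a contig edge are clipped and
    flagged ``truncated``. Unknown chromosomes raise (``strict=True``) or skip
    the gene with a warning.
    """
    records = []
    for g in genes:
        if g.chrom not in genome:
            msg = f"gene {g.gene_id}: unknown chromosome {g.chrom!r}"
            if strict:
                raise PromoterError(msg)
            warnings.warn(msg)
            continue
        if g.strand not in "+-":
            warnings.warn(f"gene {g.gene_id}: malformed strand {g.strand!r}; row rejected")
            continue
        contig = genome[g.chrom]
        if g.strand == "+":
            gstart, gend = g.tss - upstream, g.tss + downstream
        else:
            # gene-orientation position r maps to genomic g = tss − r
            gstart, gend = g.tss - downstream + 1, g.tss + upstream + 1
        cstart, cend = max(0, gstart), min(len(contig), gend)
        truncated = (cstart != gstart) or (cend != gend)
        raw = contig[cstart:cend].upper()
        if g.strand == "+":
            seq, offset = raw, g.tss - cstart
        else:
            seq, offset = revcomp(raw), (cend - 1) - g.tss
        records.append(PromoterRecord(gene_id=g.gene_id, chrom=g.chrom, tss=g.tss,
                                      strand=g.strand, seq=seq, offset_of_tss=offset,
                                      truncated=truncated))
    return records


# ---------------------------------------------------------------------------
# Near-duplicate pruning
# ---------------------------------------------------------------------------

def _kmer_counter(seq: str, k: int) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_similarity(a: str, b: str, k: int = 8) -> float:
    """Containment of k-mer multisets: |A ∩ B| / min(|A|, |B|).

    A word-composition stand-in for alignment identity: identical sequences
    score 1 and unrelated random 2-kb sequences score near 0. The word must be
    long enough that chance sharing is negligible (4^k >> sequence length);
    with short words (k = 3) random sequences already share ~90% of their
    multiset and the statistic cannot separate duplicates from noise.
    """
    ca, cb = _kmer_counter(a, k), _kmer_counter(b, k)
    inter = sum((ca & cb).values())
    denom = min(sum(ca.values()), sum(cb.values()))
    return inter / denom if denom else 0.0


def prune_similar_promoters(promoters: Sequence[PromoterRecord], threshold: float = 0.6,
                            k: int = 8) -> list[PromoterRecord]:
    """Greedy removal of promoters >``threshold`` similar to an already-retained one.

    Promoters are visited by descending length (ties by gene id) so the longest
    member of a cluster acts as its representative, mirroring greedy
    incremental sequence clustering at a 0.6 identity threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if any(not p.seq for p in promoters):
        raise ValueError("empty promoter sequence")
    order = sorted(promoters, key=lambda p: (-len(p.seq), p.gene_id))
    retained: list[PromoterRecord] = []
    kept_counters: list[Counter] = []
    for p in order:
        cp = _kmer_counter(p.seq, k)
        np_tot = sum(cp.values())
        dup = False
        for cq in kept_counters:
            inter = sum((cp & cq).values())
            if inter / min(np_tot, sum(cq.values())) > threshold:
                dup = True
                break
        if not dup:
            retained.append(p)
            kept_counters.append(cp)
    in_order = {id(p) for p in retained}
    return [p for p in promoters if id(p) in in_order]


# ---------------------------------------------------------------------------
# Gene-set splitting
# ---------------------------------------------------------------------------

@dataclass
class GeneSplit:
    """40/20/40 partition of the positives plus an even halving of the controls."""

    motif_prediction: set[str]
    feature_computation: set[str]
    model_construction: set[str]
    control_feature: set[str]
    control_model: set[str]
    seed: int

    def to_dict(self) -> dict:
        return {
            "motif_prediction": sorted(self.motif_prediction),
            "feature_computation": sorted(self.feature_computation),
            "model_construction": sorted(self.model_construction),
            "control_feature": sorted(self.control_feature),
            "control_model": sorted(self.control_model),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSplit":
        return cls(motif_prediction=set(d["motif_prediction"]),
                   feature_computation=set(d["feature_computation"]),
                   model_construction=set(d["model_construction"]),
                   control_feature=set(d["control_feature"]),
                   control_model=set(d["control_model"]),
                   seed=d["seed"])


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    by_frac = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in by_frac[:rem]:
        sizes[i] += 1
    return sizes


def split_gene_sets(positive_ids: Iterable[str], control_ids: Iterable[str],
                    seed: int) -> GeneSplit:
    """Seeded partition of positives into 40% motif-prediction / 20% feature-computation /
    40% model-construction, plus an even split of the controls into two halves.

    Deterministic given ``seed`` (largest-remainder apportionment after a seeded
    shuffle); the three positive subsets are disjoint and cover the input set.
    """
    pos = sorted(set(positive_ids))
    ctrl = sorted(set(control_ids))
    overlap = set(pos) & set(ctrl)
    if overlap:
        raise ValueError(f"positive and control sets overlap: {sorted(overlap)[:10]}")
    if len(pos) < 5:
        raise ValueError(f"need at least 5 positive genes, got {len(pos)}")
    rng = np.random.default_rng(seed)
    pos_shuf = [pos[i] for i in rng.permutation(len(pos))]
    ctrl_shuf = [ctrl[i] for i in rng.permutation(len(ctrl))]
    a, b, c = _largest_remainder(len(pos), (0.4, 0.2, 0.4))
    h1, h2 = _largest_remainder(len(ctrl), (0.5, 0.5))
    return GeneSplit(
        motif_prediction=set(pos_shuf[:a]),
        feature_computation=set(pos_shuf[a:a + b]),
        model_construction=set(pos_shuf[a + b:a + b + c]),
        control_feature=set(ctrl_shuf[:h1]),
        control_model=set(ctrl_shuf[h1:h1 + h2]),
        seed=seed,
    )
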