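"""Position weight matrices: log-odds scanning, information content, matrix
comparison for redundancy removal, and overrepresentation (ORI) statistics.

The scanner is a bespoke log-odds scanner with a *relative* score threshold
(a fraction of the maximum attainable score for the matrix), applied to both
strands of a promoter. Matrix redundancy is resolved by a Tomtom-style
comparison — minimum over all alignments with ≥1 overlapping column, in both
orientations, of the mean per-column Euclidean distance — with an empirical
p-value from random matrix pairs; the higher-information-content motif of a
redundant pair is retained.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

BASES = "ACGT"
UNIFORM = np.full(4, 0.25)

# byte-code lookup: A,C,G,T -> 0..3, anything else (incl. N) -> 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_NEG = -1e9  # effective -inf for N positions; avoids inf arithmetic


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Probability matrix over (A, C, G, T) per position.

    Rows sum to one; matrices built from counts receive a pseudocount so all
    entries are strictly positive. Motif lengths outside the 6–12 bp range
    typical of promoter motifs are allowed but warned about.
    """

    name: str
    probs: np.ndarray  # L x 4
    pseudocount: float = 0.0
    source: str = "database"  # {database, denovo}

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"{self.name}: probs must be L x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: rows must sum to 1")
        if not 6 <= len(self) <= 12:
            warnings.warn(f"motif {self.name}: length {len(self)} outside the 6-12 bp range")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.5,
                    source: str = "database") -> "PWM":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(name=name, probs=counts / counts.sum(axis=1, keepdims=True),
                   pseudocount=pseudocount, source=source)

    def reverse_complement(self) -> "PWM":
        return PWM(name=self.name, probs=self.probs[::-1, ::-1].copy(),
                   pseudocount=self.pseudocount, source=self.source)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif match inside a promoter, in gene-orientation coordinates."""

    motif: str
    gene_id: str
    start: int
    end: int
    strand: str  # relative to gene orientation
    score: float  # log-odds, bits

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("invalid occurrence coordinates")


@dataclass
class OriResult:
    motif: str
    ori: float
    pvalue: float
    n_perm: int

    @property
    def overrepresented(self) -> bool:
        return self.pvalue < 0.01


# ---------------------------------------------------------------------------
# Information content and scanning
# ---------------------------------------------------------------------------

def _check_background(background) -> np.ndarray:
    bg = UNIFORM if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be a 4-vector summing to 1")
    if np.any(bg <= 0):
        raise ValueError("background frequencies must all be positive")
    return bg


def information_content(pwm: PWM, background=None) -> float:
    """Total information content in bits: Σ_positions Σ_b p(b)·log2(p(b)/q(b))."""
    bg = _check_background(background)
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / bg), 0.0)
    return float(terms.sum())


def log_odds(pwm: PWM, background=None) -> np.ndarray:
    """L x 4 log2-odds matrix with probabilities floored to keep scores finite."""
    bg = _check_background(background)
    return np.log2(np.maximum(pwm.probs, 1e-9) / bg)


def _scan_one_strand(lo: np.ndarray, code: np.ndarray) -> np.ndarray:
    L = lo.shape[0]
    lo5 = np.hstack([lo, np.full((L, 1), _NEG)])
    win = np.lib.stride_tricks.sliding_window_view(code, L)
    return lo5[np.arange(L)[None, :], win].sum(axis=1)


def scan_sequence(pwm: PWM, seq: str, gene_id: str, background=None,
                  threshold_fraction: float = 0.8) -> list[MotifOccurrence]:
    """Log-odds scan of both strands; windows scoring ≥ threshold_fraction × max
    attainable score are reported. Positions containing N never match."""
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    L = len(pwm)
    if len(seq) < L:
        return []
    lo = log_odds(pwm, background)
    max_score = float(lo.max(axis=1).sum())
    if max_score <= 0:
        return []
    thr = threshold_fraction * max_score
    code = encode(seq)
    occs: list[MotifOccurrence] = []
    fwd = _scan_one_strand(lo, code)
    rev = _scan_one_strand(log_odds(pwm.reverse_complement(), background), code)
    for strand, scores in (("+", fwd), ("-", rev)):
        # small epsilon guards the t=1.0 exact-match case against float round-off
        for i in np.nonzero(scores >= thr - 1e-9)[0]:
            occs.append(MotifOccurrence(motif=pwm.name, gene_id=gene_id, start=int(i),
                                        end=int(i) + L, strand=strand,
                                        score=float(scores[i])))
    occs.sort(key=lambda o: (o.start, o.strand))
    return occs


def scan_promoter(pwm: PWM, promoter, background=None,
                  threshold_fraction: float = 0.8) -> list[MotifOccurrence]:
    """Scan a :class:`~promoarch.promoters.PromoterRecord` (or any object with
    ``seq`` and ``gene_id``) on both strands in gene-orientation coordinates."""
    return scan_sequence(pwm, promoter.seq, promoter.gene_id, background,
                         threshold_fraction)


def build_occurrence_index(pwms: Sequence[PWM], promoters, background=None,
                           threshold_fraction: float = 0.8) -> dict[str, list[MotifOccurrence]]:
    """Scan every promoter with every PWM: {gene_id: occurrences}."""
    index: dict[str, list[MotifOccurrence]] = {}
    for p in promoters:
        occs: list[MotifOccurrence] = []
        for pwm in pwms:
            occs.extend(scan_promoter(pwm, p, background, threshold_fraction))
        occs.sort(key=lambda o: (o.start, o.motif, o.strand))
        index[p.gene_id] = occs
    return index


# ---------------------------------------------------------------------------
# Matrix comparison and deduplication
# ---------------------------------------------------------------------------

def _aligned_distance(pa: np.ndarray, pb: np.ndarray) -> tuple[float, int, int]:
    """Min over alignments (overlap ≥ 1 column) of mean per-column Euclidean
    distance; ties (e.g. self-comparison of a repetitive motif) prefer the
    larger overlap, then the offset closest to 0."""
    la, lb = pa.shape[0], pb.shape[0]
    best = None
    for off in range(-(lb - 1), la):
        a0, a1 = max(0, off), min(la, off + lb)
        cols_a = pa[a0:a1]
        cols_b = pb[a0 - off:a1 - off]
        d = float(np.sqrt(((cols_a - cols_b) ** 2).sum(axis=1)).mean())
        key = (d, -(a1 - a0), abs(off), off)
        if best is None or key < best:
            best = key
    return best[0], best[3], -best[1]


def motif_distance(a: PWM, b: PWM, n_null: int = 1000, seed: int = 0,
                   _null_cache: dict | None = None) -> tuple[float, float, int, str]:
    """Tomtom-style comparison of two matrices.

    Returns ``(distance, pvalue, offset, orientation)`` where distance is the
    minimum mean per-column Euclidean distance over all ≥1-column alignments of
    ``b`` (either orientation) against ``a``. The p-value is empirical, from
    ``n_null`` random matrix pairs of the same lengths with columns drawn from
    a symmetric Dirichlet(1,1,1,1).
    """
    if n_null < 100:
        warnings.warn("n_null < 100 gives an unstable p-value")
    d_same, off_same, ov_same = _aligned_distance(a.probs, b.probs)
    d_rc, off_rc, ov_rc = _aligned_distance(a.probs, b.probs[::-1, ::-1])
    # orientation ties resolved by the same (distance, overlap, |offset|) key,
    # preferring the same orientation
    if (d_same, -ov_same, abs(off_same)) <= (d_rc, -ov_rc, abs(off_rc)):
        dist, offset, orient = d_same, off_same, "same"
    else:
        dist, offset, orient = d_rc, off_rc, "reverse-complement"
    null = _null_min_distances(len(a), len(b), n_null, seed, _null_cache)
    pvalue = float(np.mean(null <= dist))
    return dist, pvalue, offset, orient


def _null_min_distances(la: int, lb: int, n_null: int, seed: int,
                        cache: dict | None = None) -> np.ndarray:
    key = (min(la, lb), max(la, lb), n_null, seed)
    if cache is not None and key in cache:
        return cache[key]
    rng = np.random.default_rng(seed)
    out = np.empty(n_null)
    for i in range(n_null):
        pa = rng.dirichlet(np.ones(4), size=la)
        pb = rng.dirichlet(np.ones(4), size=lb)
        d1 = _aligned_distance(pa, pb)[0]
        d2 = _aligned_distance(pa, pb[::-1, ::-1])[0]
        out[i] = min(d1, d2)
    if cache is not None:
        cache[key] = out
    return out


def deduplicate_motifs(motifs: Sequence[PWM], p_threshold: float = 0.001,
                       background=None, n_null: int = 1000, seed: int = 0) -> list[PWM]:
    """Remove the lower-information-content motif of every similar pair (p ≤ threshold).

    All pairs are compared on the original list; ties in information content
    favour database motifs over de novo ones, then the lexicographically
    smaller name. Motifs showing no similarity to any other are retained.
    """
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names")
    ics = {m.name: information_content(m, background) for m in motifs}
    src_rank = {m.name: (0 if m.source == "database" else 1) for m in motifs}
    cache: dict = {}
    removed: set[str] = set()
    for i in range(len(motifs)):
        for j in range(i + 1, len(motifs)):
            a, b = motifs[i], motifs[j]
            _, p, _, _ = motif_distance(a, b, n_null=n_null, seed=seed, _null_cache=cache)
            if p <= p_threshold:
                # retain higher IC; tie-break: database before denovo, then name
                ka = (-ics[a.name], src_rank[a.name], a.name)
                kb = (-ics[b.name], src_rank[b.name], b.name)
                removed.add(b.name if ka <= kb else a.name)
    return [m for m in motifs if m.name not in removed]


# ---------------------------------------------------------------------------
# Overrepresentation index
# ---------------------------------------------------------------------------

def _occurrence_counts(pwm: PWM, seqs, background, threshold_fraction):
    counts = np.array([len(scan_sequence(pwm, s.seq, s.gene_id, background, threshold_fraction))
                       for s in seqs])
    lengths = np.array([len(s.seq) for s in seqs], dtype=float)
    return counts, lengths


def _ori_from_counts(counts: np.ndarray, lengths: np.ndarray, bg_density: float) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    density = total / (lengths.sum() / 1000.0)
    frac = float(np.mean(counts > 0))
    if bg_density == 0:
        return math.inf
    return (density / bg_density) * frac


def overrepresentation_index(motif: PWM, target_promoters, background_regions,
                             threshold_fraction: float = 0.8, background=None) -> float:
    """ORI = (occurrences/kb in targets ÷ occurrences/kb in background) ×
    (fraction of target promoters containing ≥1 occurrence).

    Background regions stand in for non-promoter sequence (the stretch 2–4 kb
    downstream of the TSS in the genome-scale setting). Zero background
    occurrences yield +inf.
    """
    if not len(target_promoters) or not len(background_regions):
        raise ValueError("both sequence sets must be nonempty")
    tc, tl = _occurrence_counts(motif, target_promoters, background, threshold_fraction)
    bc, bl = _occurrence_counts(motif, background_regions, background, threshold_fraction)
    bg_density = bc.sum() / (bl.sum() / 1000.0)
    return _ori_from_counts(tc, tl, bg_density)


def ori_permutation_test(motif: PWM, observed_promoters, promoter_universe,
                         background_regions, n_perm: int = 10_000, seed: int = 0,
                         threshold_fraction: float = 0.8, set_size: int | None = None,
                         background=None) -> OriResult:
    """Permutation p-value for a motif's ORI.

    Random promoter subsets of ``set_size`` (default: the observed set's size)
    are drawn from the universe and their ORIs form the reference distribution;
    p = (# random ORI strictly greater than observed) / n_perm. Deterministic
    given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    set_size = len(observed_promoters) if set_size is None else set_size
    if set_size > len(promoter_universe):
        raise ValueError("set_size exceeds the promoter universe")
    oc, ol = _occurrence_counts(motif, observed_promoters, background, threshold_fraction)
    uc, ul = _occurrence_counts(motif, promoter_universe, background, threshold_fraction)
    bc, bl = _occurrence_counts(motif, background_regions, background, threshold_fraction)
    bg_density = bc.sum() / (bl.sum() / 1000.0)
    observed = _ori_from_counts(oc, ol, bg_density)
    rng = np.random.default_rng(seed)
    n_univ = len(promoter_universe)
    greater = 0
    for _ in range(n_perm):
        idx = rng.choice(n_univ, size=set_size, replace=False)
        if _ori_from_counts(uc[idx], ul[idx], bg_density) > observed:
            greater += 1
    return OriResult(motif=motif.name, ori=observed, pvalue=greater / n_perm, n_perm=n_perm)


def select_overrepresented(pwms: Sequence[PWM], observed_promoters, promoter_universe,
                           background_regions, p_threshold: float = 0.01,
                           n_perm: int = 10_000, seed: int = 0,
                           threshold_fraction: float = 0.8, background=None) -> list[PWM]:
    """Keep motifs whose ORI permutation p-value is below ``p_threshold`` (default 0.01)."""
    kept = []
    for i, pwm in enumerate(pwms):
        res = ori_permutation_test(pwm, observed_promoters, promoter_universe,
                                   background_regions, n_perm=n_perm, seed=seed + i,
                                   threshold_fraction=threshold_fraction,
                                   background=background)
        if res.pvalue < p_threshold:
            kept.append(pwm)
    return kept
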