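"""Structural promoter features and the binary promoter × feature matrix.

Six feature classes describe a promoter's motif arrangement:

- PRESENCE: the motif occurs anywhere, any strand;
- PRESENCE_ORIENTED: the motif occurs on a specific strand;
- POSITION_TSS: the motif occurs on a specific strand with its start inside one
  of twenty half-open 100-bp windows tiling [−1500, +500) around the TSS;
- PAIR_DISTANCE: two motif occurrences (specified strands) whose start-to-start
  separation falls in a 100-bp class [0,100) … [1900,2000);
- ORDER: on one side of the TSS (upstream or downstream), an occurrence of
  motif A in a given orientation is followed (reading 5'→3' in gene
  orientation) by an occurrence of motif B in a given orientation;
- PAIR_TSS_DISTANCE: both motifs occur and the start of the one closest to the
  TSS lies in a 100-bp distance class [0,100) … [1400,1500].

Every feature is a binary predicate per promoter; the matrix over the
feature-computation and control cohorts feeds a fast correlation-based filter
(FCBF) built on symmetrical uncertainty.
"""
from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TSS_INDEX = 1500
PROMOTER_LEN = 2000

FTYPES = ("PRESENCE", "PRESENCE_ORIENTED", "POSITION_TSS", "PAIR_DISTANCE",
          "ORDER", "PAIR_TSS_DISTANCE")
_PAIR_TYPES = ("PAIR_DISTANCE", "ORDER", "PAIR_TSS_DISTANCE")

_NAME_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing parameters shared by enumeration, detection and the matrix."""

    window: int = 100
    n_position_bins: int = 20   # tile [-1500, +500)
    n_distance_bins: int = 20   # separations [0, 2000)
    n_pair_tss_bins: int = 15   # closest-to-TSS distances [0, 1500]
    ftypes: tuple = FTYPES

    def position_window(self, b: int) -> tuple[int, int]:
        lo = -TSS_INDEX + b * self.window
        return lo, lo + self.window

    def to_dict(self) -> dict:
        return {"window": self.window, "n_position_bins": self.n_position_bins,
                "n_distance_bins": self.n_distance_bins,
                "n_pair_tss_bins": self.n_pair_tss_bins,
                "ftypes": list(self.ftypes)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        d["ftypes"] = tuple(d.get("ftypes", FTYPES))
        return cls(**d)


@dataclass(frozen=True)
class FeatureDescriptor:
    """One structural feature; string form is canonical and round-trips."""

    ftype: str
    motif_a: str
    motif_b: str | None = None
    strand_a: str = "any"
    strand_b: str | None = None
    bin: int | None = None
    side: str | None = None  # {up, down} for ORDER

    def __post_init__(self):
        if self.ftype not in FTYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if (self.motif_b is not None) != (self.ftype in _PAIR_TYPES):
            raise ValueError(f"{self.ftype}: motif_b must be set iff the feature is a pair feature")
        if self.ftype == "PRESENCE" and (self.strand_a != "any" or self.bin is not None):
            raise ValueError("PRESENCE has strand any and no bin")
        if self.ftype == "PRESENCE_ORIENTED" and self.strand_a not in "+-":
            raise ValueError("PRESENCE_ORIENTED needs an explicit strand")
        if self.ftype == "POSITION_TSS" and self.bin is None:
            raise ValueError("POSITION_TSS needs a bin")
        if self.ftype == "ORDER":
            if self.strand_a not in "+-" or self.strand_b not in "+-":
                raise ValueError("ORDER needs explicit strands")
            if self.side not in ("up", "down"):
                raise ValueError("ORDER needs side in {up, down}")
        if self.ftype in ("PAIR_DISTANCE", "PAIR_TSS_DISTANCE") and self.bin is None:
            raise ValueError(f"{self.ftype} needs a bin")
        # canonicalize unordered pair features: motif_a <= motif_b, and for
        # same-motif PAIR_DISTANCE a sorted strand pair (|separation| makes
        # (+,-) and (-,+) the same predicate)
        if self.ftype in ("PAIR_DISTANCE", "PAIR_TSS_DISTANCE"):
            a, b = self.motif_a, self.motif_b
            sa = self.strand_a
            sb = self.strand_b if self.strand_b is not None else "any"
            if a > b:
                a, b, sa, sb = b, a, sb, sa
            elif a == b and sa > sb:
                sa, sb = sb, sa
            object.__setattr__(self, "motif_a", a)
            object.__setattr__(self, "motif_b", b)
            object.__setattr__(self, "strand_a", sa)
            object.__setattr__(self, "strand_b", sb)

    # -- canonical string grammar -------------------------------------------
    def __str__(self) -> str:
        c = FeatureConfig()
        if self.ftype == "PRESENCE":
            return f"PRES:{self.motif_a}"
        if self.ftype == "PRESENCE_ORIENTED":
            return f"PRESO:{self.motif_a}:{self.strand_a}"
        if self.ftype == "POSITION_TSS":
            lo, hi = c.position_window(self.bin)
            return f"POS:{self.motif_a}:{self.strand_a}:[{lo},{hi})"
        if self.ftype == "PAIR_DISTANCE":
            lo = self.bin * c.window
            return (f"PAIRD:{self.motif_a}({self.strand_a})~{self.motif_b}({self.strand_b})"
                    f":[{lo},{lo + c.window})")
        if self.ftype == "PAIR_TSS_DISTANCE":
            lo = self.bin * c.window
            return f"PAIRT:{self.motif_a}~{self.motif_b}:[{lo},{lo + c.window})"
        return (f"ORDER:{self.side}:{self.motif_a}({self.strand_a})"
                f">{self.motif_b}({self.strand_b})")

    @classmethod
    def parse(cls, s: str) -> "FeatureDescriptor":
        c = FeatureConfig()
        kind, _, rest = s.partition(":")
        if kind == "PRES":
            return cls("PRESENCE", rest)
        if kind == "PRESO":
            m, strand = rest.rsplit(":", 1)
            return cls("PRESENCE_ORIENTED", m, strand_a=strand)
        if kind == "POS":
            m, strand, win = rest.split(":")
            lo = int(win[1:].split(",")[0])
            return cls("POSITION_TSS", m, strand_a=strand, bin=(lo + TSS_INDEX) // c.window)
        if kind == "PAIRD":
            body, win = rest.rsplit(":", 1)
            ma, sa, mb, sb = re.fullmatch(r"(.+)\(([+-])\)~(.+)\(([+-])\)", body).groups()
            b = int(win[1:].split(",")[0]) // c.window
            return cls("PAIR_DISTANCE", ma, motif_b=mb, strand_a=sa, strand_b=sb, bin=b)
        if kind == "PAIRT":
            body, win = rest.rsplit(":", 1)
            ma, mb = body.split("~")
            b = int(win[1:].split(",")[0]) // c.window
            return cls("PAIR_TSS_DISTANCE", ma, motif_b=mb, strand_a="any", strand_b="any", bin=b)
        if kind == "ORDER":
            side, body = rest.split(":", 1)
            ma, sa, mb, sb = re.fullmatch(r"(.+)\(([+-])\)>(.+)\(([+-])\)", body).groups()
            return cls("ORDER", ma, motif_b=mb, strand_a=sa, strand_b=sb, side=side)
        raise ValueError(f"cannot parse feature descriptor {s!r}")

    def _key(self):
        """Canonical tuple key; aligns with the forward generator in the matrix builder."""
        f = self.ftype
        if f == "PRESENCE":
            return ("PRES", self.motif_a)
        if f == "PRESENCE_ORIENTED":
            return ("PRESO", self.motif_a, self.strand_a)
        if f == "POSITION_TSS":
            return ("POS", self.motif_a, self.strand_a, self.bin)
        if f == "PAIR_DISTANCE":
            return ("PAIRD", self.motif_a, self.motif_b, self.strand_a, self.strand_b, self.bin)
        if f == "PAIR_TSS_DISTANCE":
            return ("PAIRT", self.motif_a, self.motif_b, self.bin)
        return ("ORDER", self.side, self.motif_a, self.strand_a, self.motif_b, self.strand_b)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def enumerate_candidate_features(motif_names: Sequence[str],
                                 config: FeatureConfig | None = None) -> list[FeatureDescriptor]:
    """Enumerate every candidate feature for the given motifs, in canonical order.

    Feature count for M motifs with default windowing::

        M (presence) + 2M (oriented) + 40M (position)
        + 20 * (4*C(M,2) + 3M)   (pair-distance; self-pairs have 3 strand combos)
        + 15 * M(M+1)/2          (pair-to-TSS distance)
        + 8 * M^2                (order: 4 orientation combos x 2 sides)
    """
    config = config or FeatureConfig()
    names = sorted(set(motif_names))
    if len(names) != len(motif_names):
        raise ValueError("duplicate motif names")
    for n in names:
        if not _NAME_RE.match(n):
            raise ValueError(f"motif name {n!r} contains characters outside [A-Za-z0-9_.-]")
    out: list[FeatureDescriptor] = []
    if "PRESENCE" in config.ftypes:
        out += [FeatureDescriptor("PRESENCE", m) for m in names]
    if "PRESENCE_ORIENTED" in config.ftypes:
        out += [FeatureDescriptor("PRESENCE_ORIENTED", m, strand_a=s)
                for m in names for s in "+-"]
    if "POSITION_TSS" in config.ftypes:
        out += [FeatureDescriptor("POSITION_TSS", m, strand_a=s, bin=b)
                for m in names for s in "+-" for b in range(config.n_position_bins)]
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i:]]
    if "PAIR_DISTANCE" in config.ftypes:
        for a, b in pairs:
            combos = ([("+", "+"), ("+", "-"), ("-", "-")] if a == b
                      else [("+", "+"), ("+", "-"), ("-", "+"), ("-", "-")])
            out += [FeatureDescriptor("PAIR_DISTANCE", a, motif_b=b, strand_a=sa,
                                      strand_b=sb, bin=k)
                    for sa, sb in combos for k in range(config.n_distance_bins)]
    if "PAIR_TSS_DISTANCE" in config.ftypes:
        out += [FeatureDescriptor("PAIR_TSS_DISTANCE", a, motif_b=b, strand_a="any",
                                  strand_b="any", bin=k)
                for a, b in pairs for k in range(config.n_pair_tss_bins)]
    if "ORDER" in config.ftypes:
        out += [FeatureDescriptor("ORDER", a, motif_b=b, strand_a=sa, strand_b=sb, side=side)
                for a in names for b in names for sa in "+-" for sb in "+-"
                for side in ("up", "down")]
    return out


# ---------------------------------------------------------------------------
# Detection / counting
# ---------------------------------------------------------------------------

def _starts(occs, motif: str, strand: str) -> list[int]:
    if strand == "any":
        return sorted(o.start for o in occs if o.motif == motif)
    return sorted(o.start for o in occs if o.motif == motif and o.strand == strand)


def _pair_instances(occs, f: FeatureDescriptor):
    """Yield qualifying (start_a, start_b) instance pairs for a pair feature.

    Same-motif pairs with symmetric strand specs are counted once per unordered
    occurrence pair.
    """
    same = f.motif_a == f.motif_b
    if f.ftype == "ORDER":
        lo, hi = (0, TSS_INDEX) if f.side == "up" else (TSS_INDEX, PROMOTER_LEN)
        sa = [s for s in _starts(occs, f.motif_a, f.strand_a) if lo <= s < hi]
        sb = [s for s in _starts(occs, f.motif_b, f.strand_b) if lo <= s < hi]
        for x in sa:
            for y in sb:
                if x < y:
                    yield x, y
        return
    sa = _starts(occs, f.motif_a, f.strand_a)
    sb = _starts(occs, f.motif_b, f.strand_b if f.strand_b else "any")
    if same and f.strand_a == (f.strand_b or "any"):
        for i in range(len(sa)):
            for j in range(i + 1, len(sa)):
                yield sa[i], sa[j]
    elif same:
        # distinct strand specs on the same motif: one occurrence per spec,
        # unordered, so each cross pair counts once
        for x in sa:
            for y in sb:
                yield x, y
    else:
        for x in sa:
            for y in sb:
                yield x, y


def count_feature(f: FeatureDescriptor, occs, config: FeatureConfig | None = None) -> int:
    """Number of qualifying instantiations of a feature in one promoter's occurrences
    (occurrences for single-motif features, occurrence pairs for pair features)."""
    config = config or FeatureConfig()
    w = config.window
    if f.ftype == "PRESENCE":
        return len(_starts(occs, f.motif_a, "any"))
    if f.ftype == "PRESENCE_ORIENTED":
        return len(_starts(occs, f.motif_a, f.strand_a))
    if f.ftype == "POSITION_TSS":
        lo, hi = config.position_window(f.bin)
        return sum(1 for s in _starts(occs, f.motif_a, f.strand_a)
                   if lo <= s - TSS_INDEX < hi)
    if f.ftype == "PAIR_DISTANCE":
        lo, hi = f.bin * w, (f.bin + 1) * w
        return sum(1 for x, y in _pair_instances(occs, f) if lo <= abs(y - x) < hi)
    if f.ftype == "PAIR_TSS_DISTANCE":
        n = 0
        for x, y in _pair_instances(occs, f):
            d = min(abs(x - TSS_INDEX), abs(y - TSS_INDEX))
            if min(d // w, config.n_pair_tss_bins - 1) == f.bin:
                n += 1
        return n
    return sum(1 for _ in _pair_instances(occs, f))  # ORDER


def detect_feature(f: FeatureDescriptor, occs, config: FeatureConfig | None = None) -> int:
    """1 iff the feature has at least one qualifying instantiation."""
    return 1 if count_feature(f, occs, config) > 0 else 0


def occurrence_feature_counts(occs, config: FeatureConfig | None = None) -> Counter:
    """Forward-generate the canonical-key counts of every feature active in one
    promoter; equivalent to ``count_feature`` over the full enumeration but a
    single pass over occurrence pairs."""
    config = config or FeatureConfig()
    w = config.window
    counts: Counter = Counter()
    occ = sorted(occs, key=lambda o: (o.start, o.motif, o.strand))
    for o in occ:
        counts[("PRES", o.motif)] += 1
        counts[("PRESO", o.motif, o.strand)] += 1
        counts[("POS", o.motif, o.strand, o.start // w)] += 1
    for i in range(len(occ)):
        for j in range(i + 1, len(occ)):
            a, b_ = occ[i], occ[j]  # a.start <= b_.start
            # unordered pair with canonical motif (and strand, for self-pairs) order
            ma, sa, mb, sb = a.motif, a.strand, b_.motif, b_.strand
            if ma > mb or (ma == mb and sa > sb):
                ma, sa, mb, sb = mb, sb, ma, sa
            sep = abs(b_.start - a.start)
            counts[("PAIRD", ma, mb, sa, sb, sep // w)] += 1
            d = min(abs(a.start - TSS_INDEX), abs(b_.start - TSS_INDEX))
            counts[("PAIRT", ma, mb, min(d // w, config.n_pair_tss_bins - 1))] += 1
            if a.start < b_.start:
                side = None
                if b_.start < TSS_INDEX:
                    side = "up"
                elif a.start >= TSS_INDEX:
                    side = "down"
                if side is not None:
                    counts[("ORDER", side, a.motif, a.strand, b_.motif, b_.strand)] += 1
    return counts


# ---------------------------------------------------------------------------
# Binary matrix
# ---------------------------------------------------------------------------

@dataclass
class BinaryFeatureMatrix:
    """Promoters × features presence/absence matrix with class labels
    (1 = positive, 0 = control)."""

    genes: list[str]
    features: list[FeatureDescriptor]
    values: np.ndarray  # uint8, genes x features
    labels: np.ndarray  # int8, 1 positive / 0 control
    config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.values.shape != (len(self.genes), len(self.features)):
            raise ValueError("matrix shape does not match genes x features")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    def restrict_genes(self, gene_ids: Iterable[str]) -> "BinaryFeatureMatrix":
        keep = set(gene_ids)
        idx = [i for i, g in enumerate(self.genes) if g in keep]
        return BinaryFeatureMatrix([self.genes[i] for i in idx], self.features,
                                   self.values[idx], self.labels[idx], self.config)

    def restrict_features(self, features: Sequence[FeatureDescriptor]) -> "BinaryFeatureMatrix":
        pos = {str(f): i for i, f in enumerate(self.features)}
        idx = [pos[str(f)] for f in features]
        return BinaryFeatureMatrix(self.genes, list(features), self.values[:, idx],
                                   self.labels, self.config)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.genes,
                          columns=[str(f) for f in self.features])
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, config: FeatureConfig | None = None) -> "BinaryFeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        labels = df.pop("label").to_numpy(dtype=np.int8)
        feats = [FeatureDescriptor.parse(c) for c in df.columns]
        return cls(list(df.index), feats, df.to_numpy(dtype=np.uint8), labels,
                   config or FeatureConfig())


def build_feature_matrix(features: Sequence[FeatureDescriptor],
                         occurrence_index: dict,
                         positive_ids: Iterable[str], control_ids: Iterable[str],
                         config: FeatureConfig | None = None) -> BinaryFeatureMatrix:
    """values[g, f] = detect_feature(f, occurrences[g]); labels from the id sets.

    Detection runs through a forward pass that generates the canonical key of
    every feature instantiated by the promoter's occurrences (verified
    equivalent to per-feature detection in the test suite).
    """
    config = config or FeatureConfig()
    pos = sorted(set(positive_ids))
    ctrl = sorted(set(control_ids))
    both = set(pos) & set(ctrl)
    if both:
        raise ValueError(f"ids in both classes: {sorted(both)[:10]}")
    genes = pos + ctrl
    missing = [g for g in genes if g not in occurrence_index]
    if missing:
        raise KeyError(f"no occurrence list for genes: {missing[:10]}")
    col = {f._key(): i for i, f in enumerate(features)}
    values = np.zeros((len(genes), len(features)), dtype=np.uint8)
    for gi, g in enumerate(genes):
        for key in occurrence_feature_counts(occurrence_index[g], config):
            ci = col.get(key)
            if ci is not None:
                values[gi, ci] = 1
    labels = np.array([1] * len(pos) + [0] * len(ctrl), dtype=np.int8)
    return BinaryFeatureMatrix(genes, list(features), values, labels, config)


# ---------------------------------------------------------------------------
# Symmetrical uncertainty and the FCBF correlation filter
# ---------------------------------------------------------------------------

def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x, y) -> float:
    """SU(X,Y) = 2·IG(X;Y) / (H(X)+H(Y)) in bits; 0 when either variable is constant."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("columns must have the same length")
    hx = _entropy_bits(np.bincount(x.astype(np.int64)))
    hy = _entropy_bits(np.bincount(y.astype(np.int64)))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    joint = np.bincount(x.astype(np.int64) * 2 + y.astype(np.int64), minlength=4)
    ig = hx + hy - _entropy_bits(joint)
    return 2.0 * ig / (hx + hy)


def _su_one_vs_all(x: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized SU between a binary column and every column of X."""
    n = x.shape[0]
    sx = float(x.sum())
    s = X.sum(axis=0).astype(float)
    n11 = x.astype(np.float64) @ X.astype(np.float64)
    n10 = sx - n11
    n01 = s - n11
    n00 = n - n11 - n10 - n01

    def h(*cs):
        tot = np.zeros_like(cs[0], dtype=float)
        for c in cs:
            p = c / n
            with np.errstate(divide="ignore", invalid="ignore"):
                tot -= np.where(p > 0, p * np.log2(p), 0.0)
        return tot

    hx = h(np.full_like(s, sx), np.full_like(s, n - sx))
    hy = h(s, n - s)
    hxy = h(n11, n10, n01, n00)
    denom = hx + hy
    with np.errstate(divide="ignore", invalid="ignore"):
        su = np.where(denom > 0, 2.0 * (hx + hy - hxy) / denom, 0.0)
    return np.clip(su, 0.0, 1.0)


def correlation_filter(matrix: BinaryFeatureMatrix, delta: float = 0.0) -> list[FeatureDescriptor]:
    """FCBF: rank features by SU with the class label, drop those below ``delta``,
    then remove every feature that has a *predominant* one — a higher-ranked
    retained feature whose SU with it is ≥ its SU with the class.

    Deterministic: SU ties keep the canonical (input) feature order, and the
    predominance comparison carries a 1e-12 tolerance so algebraically equal
    SU values (identical contingency tables) compare as equal despite
    floating-point noise.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    labels = matrix.labels.astype(np.uint8)
    if labels.min() == labels.max():
        raise ValueError("matrix must contain both classes")
    X = matrix.values
    su_c = np.round(_su_one_vs_all(labels, X), 12)  # stabilize tie order
    order = sorted(range(len(matrix.features)), key=lambda i: (-su_c[i], i))
    order = [i for i in order if su_c[i] >= delta]
    retained_idx: list[int] = []
    retained_rows: list[np.ndarray] = []
    for i in order:
        predominant = any(row[i] >= su_c[i] - 1e-12 for row in retained_rows)
        if predominant:
            continue
        retained_idx.append(i)
        retained_rows.append(_su_one_vs_all(X[:, i], X))
    if not retained_idx:
        warnings.warn("correlation filter removed every feature")
    return [matrix.features[i] for i in retained_idx]
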