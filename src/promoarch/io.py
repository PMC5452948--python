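"""Plain-text format I/O: FASTA, BED-like gene tables, gene-id lists, motif files, occurrence BED.

Sequence and motif parsing is delegated to Biopython (Bio.SeqIO, Bio.motifs); the
functions here only adapt those records to the package's in-memory types.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio import motifs as bio_motifs

BASES = "ACGT"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA file into {id: sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables and id lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRow:
    """One gene: chromosome, TSS coordinate (0-based) and strand."""
    chrom: str
    tss: int
    strand: str
    gene_id: str


def read_gene_table(path, tss_at: str = "five_prime") -> list[GeneRow]:
    """Read a BED6-style gene table (chrom, start, end, name, score, strand).

    ``tss_at`` declares where the TSS sits in each interval:

    - ``"five_prime"``: TSS = start for '+' genes and end−1 for '−' genes
      (the interval is the transcript in genomic orientation);
    - ``"start"``: TSS = start regardless of strand (the table stores TSS points).

    Rows with a malformed strand are rejected (skipped) per the record contract.
    """
    if tss_at not in ("five_prime", "start"):
        raise ValueError(f"unknown tss_at convention {tss_at!r}")
    rows: list[GeneRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                parts = line.split()
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            if strand not in "+-":
                continue  # rejected row
            if tss_at == "five_prime":
                tss = start if strand == "+" else end - 1
            else:
                tss = start
            rows.append(GeneRow(chrom=chrom, tss=tss, strand=strand, gene_id=name))
    return rows


def read_id_list(path) -> list[str]:
    """Read a plain-text, one-id-per-line gene list (blank lines and # comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_id_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# Motif matrices (JASPAR PFM / MEME minimal)
# ---------------------------------------------------------------------------

def read_jaspar(path, pseudocount: float = 0.5):
    """Read JASPAR-format PFM files into a list of :class:`promoarch.motifs.PWM`."""
    from .motifs import PWM

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in parsed:
            counts = np.array([list(m.counts[b]) for b in BASES], dtype=float).T  # L x 4
            name = m.name or m.matrix_id
            out.append(PWM.from_counts(name, counts, pseudocount=pseudocount, source="database"))
    return out


def read_meme_minimal(path, pseudocount: float = 1e-4):
    """Read MEME minimal-format motif files into PWMs.

    MEME minimal stores probability matrices; a small pseudocount keeps every
    entry strictly positive so log-odds scores stay finite.
    """
    from .motifs import PWM

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
        out = []
        for m in parsed:
            probs = np.array([list(m.pwm[b]) for b in BASES], dtype=float).T
            probs = probs + pseudocount
            probs = probs / probs.sum(axis=1, keepdims=True)
            out.append(PWM(name=m.name, probs=probs, source="database"))
    return out


def write_jaspar(pwms, path) -> None:
    """Write PWMs as JASPAR PFMs (probabilities; JASPAR tolerates float matrices)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.6f}" for v in pwm.probs[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Occurrences and intervals as BED
# ---------------------------------------------------------------------------

def write_occurrences_bed(occs, path) -> None:
    """Write motif occurrences as BED6: gene_id, start, end, motif, log-odds score, strand."""
    with open(path, "w") as fh:
        for o in occs:
            fh.write(f"{o.gene_id}\t{o.start}\t{o.end}\t{o.motif}\t{o.score:.4f}\t{o.strand}\n")


def read_occurrences_bed(path):
    from .motifs import MotifOccurrence

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            gene, start, end, motif, score, strand = line.split("\t")
            out.append(MotifOccurrence(motif=motif, gene_id=gene, start=int(start),
                                       end=int(end), strand=strand, score=float(score)))
    return out


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read a BED file as (chrom, start, end) tuples; extra columns ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
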