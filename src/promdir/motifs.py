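"""Strand-aware motif scanning, TSS-relative occurrence profiles, enrichment.

Motifs are short patterns over {A,C,G,T} with optional single-position
alternatives written in brackets: the A-track is ``AAAAAAA`` and the GC-rich
motif ``CG[CG]G``. Scanning reports every match start, overlapping matches
included; ``N`` never matches. Antisense scanning means scanning the reverse
complement and mapping each match back to the leftmost base of its footprint
in input coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .annotation import GeneRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

A_TRACK = None  # filled below
GC_MOTIF = None


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _parse_pattern(pattern: str) -> tuple[frozenset, ...]:
    positions = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            alts = frozenset(pattern[i + 1:j].upper())
            if not alts or not alts <= set("ACGT"):
                raise ValueError(f"bad alternative set in pattern {pattern!r}")
            positions.append(alts)
            i = j + 1
        else:
            if ch.upper() not in "ACGT":
                raise ValueError(f"bad base {ch!r} in pattern {pattern!r}")
            positions.append(frozenset(ch.upper()))
            i += 1
    if not positions:
        raise ValueError("empty motif pattern")
    return tuple(positions)


@dataclass(frozen=True)
class MotifSpec:
    """A named pattern with strand semantics.

    ``scan_strand='sense'`` scans the given sequence as-is; ``'antisense'``
    scans its reverse complement.
    """

    name: str
    pattern: str
    scan_strand: str = "sense"

    def __post_init__(self):
        if self.scan_strand not in {"sense", "antisense"}:
            raise ValueError("scan_strand must be 'sense' or 'antisense'")
        _parse_pattern(self.pattern)  # validate

    @property
    def positions(self) -> tuple[frozenset, ...]:
        return _parse_pattern(self.pattern)

    def __len__(self) -> int:
        return len(self.positions)

    def regex(self) -> re.Pattern:
        body = "".join("[%s]" % "".join(sorted(s)) for s in self.positions)
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


A_TRACK = MotifSpec("A-track", "AAAAAAA")
GC_MOTIF = MotifSpec("CG(C/G)G", "CG[CG]G")


def scan_motif(sequence: str, motif: MotifSpec) -> list[int]:
    """All match start positions, ascending, overlapping matches allowed.

    For an antisense motif the reverse complement is scanned and each match
    mapped back to the leftmost base of its footprint in input coordinates.
    """
    seq = sequence.upper()
    m = len(motif)
    if motif.scan_strand == "antisense":
        seq = reverse_complement(seq)
    starts = [match.start() for match in motif.regex().finditer(seq)]
    if motif.scan_strand == "antisense":
        L = len(seq)
        starts = sorted(L - s - m for s in starts)
    return starts


def _oriented_promoter_seq(g: GeneRecord, genome: Mapping[str, str],
                           flank: int) -> str | None:
    """Promoter sequence on the coding strand, TSS at index ``flank``.

    Index i corresponds to offset i - flank from the TSS in the direction of
    transcription. Returns None (to be skipped) when the span leaves the
    chromosome.
    """
    if g.chrom not in genome:
        raise KeyError(f"genome lacks chromosome {g.chrom!r}")
    chrom_seq = genome[g.chrom]
    if g.strand == "+":
        lo, hi = g.tss - flank, g.tss + flank
        if lo < 0 or hi > len(chrom_seq):
            return None
        return chrom_seq[lo:hi].upper()
    lo, hi = g.tss - flank + 1, g.tss + flank + 1
    if lo < 0 or hi > len(chrom_seq):
        return None
    return reverse_complement(chrom_seq[lo:hi])


@dataclass
class MotifProfile:
    group: str
    strand: str                 # the motif's scan strand
    offsets: np.ndarray         # -flank .. flank-1, TSS = 0
    fraction: np.ndarray        # per offset: fraction of promoters with a match start
    n_genes: int


def motif_profile(
    genes: Sequence[GeneRecord],
    genome: Mapping[str, str],
    motif: MotifSpec,
    flank: int = 500,
    group: str = "all",
) -> MotifProfile:
    """Positional motif-occurrence profile around the TSS.

    Promoter sequences are strand-oriented before scanning, so "sense"
    always means the coding strand; genes whose +/-flank span overhangs the
    chromosome are skipped and logged.
    """
    hits = np.zeros(2 * flank, dtype=float)
    n_used = 0
    n_skipped = 0
    for g in genes:
        seq = _oriented_promoter_seq(g, genome, flank)
        if seq is None:
            n_skipped += 1
            continue
        n_used += 1
        indicator = np.zeros(2 * flank, dtype=bool)
        for s in scan_motif(seq, motif):
            indicator[s] = True
        hits += indicator
    if n_skipped:
        logger.info("motif_profile: skipped %d genes overhanging chromosome "
                    "ends", n_skipped)
    fraction = hits / n_used if n_used else hits
    return MotifProfile(group=group, strand=motif.scan_strand,
                        offsets=np.arange(-flank, flank),
                        fraction=fraction, n_genes=n_used)


def _per_promoter_counts(genes, genome, motif, flank) -> np.ndarray:
    counts = []
    for g in genes:
        seq = _oriented_promoter_seq(g, genome, flank)
        if seq is None:
            continue
        counts.append(len(scan_motif(seq, motif)))
    return np.asarray(counts, dtype=float)


@dataclass
class EnrichmentResult:
    fold_enrichment: float
    p_value: float
    higher_group: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def motif_enrichment(
    groupA_genes: Sequence[GeneRecord],
    groupB_genes: Sequence[GeneRecord],
    genome: Mapping[str, str],
    motif: MotifSpec,
    flank: int = 500,
) -> EnrichmentResult:
    """Compare per-promoter match counts between two promoter groups.

    Fold enrichment is the ratio of group means with a pseudocount of 0.5
    added to each mean; the p-value is a two-sided Mann-Whitney rank-sum
    test on the per-promoter counts.
    """
    if len(groupA_genes) == 0 or len(groupB_genes) == 0:
        raise ValueError("both promoter groups must be nonempty")
    a = _per_promoter_counts(groupA_genes, genome, motif, flank)
    b = _per_promoter_counts(groupB_genes, genome, motif, flank)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = (mean_a + 0.5) / (mean_b + 0.5)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        p = 1.0  # no variation anywhere: no evidence either way
    else:
        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    higher = "A" if mean_a > mean_b else ("B" if mean_b > mean_a else "tie")
    return EnrichmentResult(fold_enrichment=float(fold), p_value=p,
                            higher_group=higher, mean_a=mean_a, mean_b=mean_b,
                            n_a=len(a), n_b=len(b))


def read_fasta(path) -> dict[str, str]:
    """Sequential whole-genome FASTA load (desk-scale genomes)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
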