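"""Strand-specific single-nucleotide end coverage and window counting.

Each sequenced fragment is reduced to a single base — by default its 3'
terminal nucleotide on the transcript strand — and accumulated into dense
per-chromosome, per-strand vectors. Promoter windows (+1..+500 downstream of
the TSS on the coding strand; -1..-500 upstream on the opposite strand) and
arbitrary anchored intervals are counted directly off those vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .annotation import GeneRecord

END_CONVENTIONS = {"3prime", "5prime"}
STRANDNESS = {"forward", "reverse"}
_FLIP = {"+": "-", "-": "+"}


class CoverageError(ValueError):
    pass


@dataclass
class StrandedCoverage:
    """Dense per-base end-coverage, one vector per (chromosome, strand)."""

    chrom_sizes: dict[str, int]
    data: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    sample_id: str | None = None
    end_convention: str = "3prime"

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int], sample_id: str | None = None,
              end_convention: str = "3prime") -> "StrandedCoverage":
        data = {
            c: {"+": np.zeros(n, dtype=np.float64),
                "-": np.zeros(n, dtype=np.float64)}
            for c, n in chrom_sizes.items()
        }
        return cls(dict(chrom_sizes), data, sample_id, end_convention)

    def vector(self, chrom: str, strand: str) -> np.ndarray:
        if chrom not in self.data:
            raise CoverageError(f"unknown chromosome {chrom!r}")
        if strand not in _FLIP:
            raise CoverageError(f"unknown strand {strand!r}")
        return self.data[chrom][strand]

    def total_signal(self, strand: str | None = None) -> float:
        strands = [strand] if strand else ["+", "-"]
        return float(sum(self.data[c][s].sum()
                         for c in self.data for s in strands))


def fragments_to_end_coverage(
    fragments: Iterable[tuple[str, int, int, str]],
    chrom_sizes: Mapping[str, int],
    end_convention: str = "3prime",
    library_strandness: str = "reverse",
    sample_id: str | None = None,
) -> StrandedCoverage:
    """Reduce each fragment to its 3' (or 5') terminal base on the transcript
    strand and accumulate one unit there.

    ``library_strandness`` maps the fragment's recorded orientation to the
    transcript strand: ``forward`` keeps it, ``reverse`` (typical dUTP-based
    stranded libraries) flips it. Totals are conserved exactly: one unit per
    fragment.
    """
    if end_convention not in END_CONVENTIONS:
        raise ValueError(f"end_convention must be one of {END_CONVENTIONS}")
    if library_strandness not in STRANDNESS:
        raise ValueError(f"library_strandness must be one of {STRANDNESS}")
    cov = StrandedCoverage.zeros(chrom_sizes, sample_id, end_convention)
    for frag in fragments:
        chrom, start, end, strand = frag[0], int(frag[1]), int(frag[2]), frag[-1]
        if chrom not in cov.data:
            raise CoverageError(f"fragment on unknown chromosome: {frag!r}")
        size = cov.chrom_sizes[chrom]
        if not (0 <= start < end <= size):
            raise CoverageError(f"fragment outside chromosome bounds: {frag!r}")
        if strand not in _FLIP:
            raise CoverageError(f"fragment with unknown strand: {frag!r}")
        tstrand = strand if library_strandness == "forward" else _FLIP[strand]
        if end_convention == "3prime":
            pos = end - 1 if tstrand == "+" else start
        else:
            pos = start if tstrand == "+" else end - 1
        cov.data[chrom][tstrand][pos] += 1
    return cov


def read_bed6_fragments(path: str | Path) -> Iterator[tuple[str, int, int, str]]:
    """Yield (chrom, start, end, strand) from a BED6 fragment file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise CoverageError(
                    f"{path}, line {lineno}: expected 6 BED columns")
            yield fields[0], int(fields[1]), int(fields[2]), fields[5]


def write_bedgraph(cov: StrandedCoverage, strand: str, path: str | Path) -> None:
    """Write one strand of the coverage as sorted bedGraph; zero runs omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(cov.data):
            vec = cov.vector(chrom, strand)
            if vec.size == 0:
                continue
            # run-length encode: boundaries where the value changes
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v == 0:
                    continue
                vstr = str(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{s}\t{e}\t{vstr}\n")


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    strand: str,
    cov: StrandedCoverage | None = None,
) -> StrandedCoverage:
    """Read a bedGraph file into the given strand of a coverage object.

    Intervals must be sorted and non-overlapping per chromosome; unknown
    chromosomes and overlaps raise :class:`CoverageError`. Pass an existing
    ``cov`` to fill the second strand of a pair.
    """
    if cov is None:
        cov = StrandedCoverage.zeros(chrom_sizes)
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise CoverageError(
                    f"{path}, line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            if chrom not in cov.data:
                raise CoverageError(
                    f"{path}, line {lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= cov.chrom_sizes[chrom]):
                raise CoverageError(
                    f"{path}, line {lineno}: interval outside chromosome")
            if start < last_end.get(chrom, 0):
                raise CoverageError(
                    f"{path}, line {lineno}: overlapping/unsorted intervals")
            last_end[chrom] = end
            cov.vector(chrom, strand)[start:end] += value
    return cov


def read_bedgraph_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str | None = None,
) -> StrandedCoverage:
    cov = StrandedCoverage.zeros(chrom_sizes, sample_id=sample_id)
    read_bedgraph(plus_path, chrom_sizes, "+", cov)
    read_bedgraph(minus_path, chrom_sizes, "-", cov)
    return cov


def count_window(cov: StrandedCoverage, chrom: str, strand: str,
                 start: int, end: int) -> float:
    """Sum the strand's vector over [start, end). The window must lie inside
    the chromosome; callers clip explicitly if they want truncation."""
    vec = cov.vector(chrom, strand)
    if not (0 <= start < end <= vec.size):
        raise CoverageError(
            f"window [{start},{end}) outside chromosome {chrom} "
            f"(length {vec.size})")
    return float(vec[start:end].sum())


@dataclass(frozen=True)
class WindowCounts:
    gene_id: str
    sense_count: float
    antisense_count: float
    clipped: bool = False


def _promoter_windows(g: GeneRecord, window: int):
    """Genomic spans of the sense and antisense promoter windows.

    Returns ((sense_start, sense_end, sense_strand),
             (anti_start, anti_end, anti_strand)) with the sense window
    covering positions +1..+window downstream of the TSS in the coding
    direction and the antisense window -1..-window upstream on the opposite
    strand.
    """
    t = g.tss
    if g.strand == "+":
        return (t, t + window, "+"), (t - window, t, "-")
    return (t - window + 1, t + 1, "-"), (t + 1, t + window + 1, "+")


def count_promoter_windows(
    genes: Sequence[GeneRecord],
    cov: StrandedCoverage,
    window: int = 500,
) -> list[WindowCounts]:
    """Count sense/antisense promoter-window signal for every gene.

    Windows reaching past a chromosome edge are truncated to the available
    span and flagged ``clipped`` rather than dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = []
    for g in genes:
        size = cov.chrom_sizes.get(g.chrom)
        if size is None:
            raise CoverageError(f"gene {g.gene_id} on unknown chromosome "
                                f"{g.chrom!r}")
        (ss, se, sstr), (as_, ae, astr) = _promoter_windows(g, window)
        clipped = ss < 0 or as_ < 0 or se > size or ae > size
        ss, as_ = max(ss, 0), max(as_, 0)
        se, ae = min(se, size), min(ae, size)
        sense = count_window(cov, g.chrom, sstr, ss, se) if ss < se else 0.0
        anti = count_window(cov, g.chrom, astr, as_, ae) if as_ < ae else 0.0
        out.append(WindowCounts(g.gene_id, sense, anti, clipped))
    return out


def count_anchored_intervals(
    anchors: Sequence[tuple],
    cov: StrandedCoverage,
    flank: int = 100,
) -> list[dict]:
    """Count signal in [pos-flank, pos+flank) around each anchor, separately
    per strand: n anchors yield exactly 2n rows.

    Anchors are (chrom, position) or (chrom, position, strand) tuples; the
    anchor's own strand, when present, is carried through as metadata only.
    """
    rows = []
    for anchor in anchors:
        chrom, pos = anchor[0], int(anchor[1])
        astrand = anchor[2] if len(anchor) > 2 else "."
        size = cov.chrom_sizes.get(chrom)
        if size is None:
            raise CoverageError(f"anchor on unknown chromosome {chrom!r}")
        lo, hi = pos - flank, pos + flank
        if lo < 0 or hi > size:
            raise CoverageError(
                f"anchor interval [{lo},{hi}) outside chromosome {chrom}")
        for strand in ("+", "-"):
            rows.append({
                "chrom": chrom, "pos": pos, "anchor_strand": astrand,
                "count_strand": strand,
                "count": count_window(cov, chrom, strand, lo, hi),
            })
    return rows
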