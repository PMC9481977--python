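"""Gene annotation handling: parsing, TSS curation, and promoter classification.

Coordinates are 0-based half-open everywhere inside the package. GFF3 input
(1-based, inclusive) is converted at parse time; BED6 is native. The TSS of a
plus-strand gene is its leftmost base, of a minus-strand gene its rightmost
base, unless replaced by a curated entry.

Promoters are classified as ``tandem``, ``divergent`` or ``overlapping``.
Only tandem promoters enter the directionality analysis: the 500-bp window
upstream of a tandem TSS cannot contain another gene's coding transcription,
so signal there can be attributed to divergent noncoding initiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-"}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated transcript/gene with strand and a single TSS.

    ``start``/``end`` are 0-based half-open; ``tss`` defaults to the
    strand-appropriate gene boundary and is marked ``tss_source='curated'``
    when replaced from a curated table.
    """

    chrom: str
    start: int
    gene_id: str
    end: int
    strand: str
    tss: int = field(default=-1)
    tss_source: str = "annotation"

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        if self.tss < 0:
            object.__setattr__(self, "tss", self.default_tss())

    def default_tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PromoterClass:
    gene_id: str
    label: str  # tandem | divergent | overlapping


def _sorted_unique(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    out = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    seen: set[str] = set()
    for g in out:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return out


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(
    path: str | Path,
    format: str = "GFF3",
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneRecord]:
    """Read gene records from GFF3 or BED6.

    Returns records sorted by (chrom, start, gene_id). GFF3 coordinates are
    converted from 1-based inclusive to 0-based half-open. Malformed lines
    raise :class:`AnnotationError` naming the line number.
    """
    fmt = format.upper()
    if fmt not in {"GFF3", "BED6", "BED"}:
        raise ValueError(f"unsupported annotation format {format!r}")
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "GFF3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated columns")
                    chrom, _, ftype, start1, end1, _, strand, _, attrs = fields[:9]
                    if ftype not in feature_types:
                        continue
                    attrd = _parse_gff3_attributes(attrs)
                    gid = attrd.get("ID") or attrd.get("gene_id") or attrd.get("Name")
                    if gid is None:
                        raise ValueError("no ID/gene_id/Name attribute")
                    gid = gid.removeprefix("gene:")
                    start = int(start1) - 1
                    end = int(end1)
                else:
                    if len(fields) < 6:
                        raise ValueError("expected 6 tab-separated columns")
                    chrom, start_, end_, gid, _, strand = fields[:6]
                    start = int(start_)
                    end = int(end_)
                genes.append(
                    GeneRecord(chrom=chrom, start=start, gene_id=gid, end=end,
                               strand=strand)
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}, line {lineno}: {exc}") from exc
    return _sorted_unique(genes)


def write_annotation(genes: Iterable[GeneRecord], path: str | Path,
                     format: str = "GFF3") -> None:
    """Write gene records as GFF3 or BED6 (round-trips with read_annotation)."""
    fmt = format.upper()
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tpromdir\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
        elif fmt in {"BED6", "BED"}:
            for g in genes:
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                )
        else:
            raise ValueError(f"unsupported annotation format {format!r}")


def read_tss_table(path: str | Path) -> dict[str, int]:
    """Read a curated TSS table: 2-column TSV (gene_id, tss_1based), header row.

    Positions are converted to 0-based. An optional third column names the
    chromosome and is returned packed as ``(chrom, pos)``.
    """
    table: dict = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() == "":
            return table
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise AnnotationError(
                    f"{path}, line {lineno}: expected at least 2 columns")
            gid, pos1 = fields[0], int(fields[1])
            if len(fields) >= 3 and fields[2]:
                table[gid] = (fields[2], pos1 - 1)
            else:
                table[gid] = pos1 - 1
    return table


def apply_curated_tss(
    genes: Iterable[GeneRecord],
    tss_table: Mapping[str, int | tuple[str, int]],
) -> list[GeneRecord]:
    """Replace annotation TSSs with curated positions where available.

    The curated list is primary; genes absent from the table keep the
    annotation-derived TSS. A curated position downstream of the gene end
    (past the 3' boundary, so it cannot be a start site of this gene) is
    ignored with a logged warning; a curated entry carrying a chromosome
    that disagrees with the gene's raises an error. Unknown gene ids in the
    table are ignored with a warning.
    """
    genes = _sorted_unique(genes)
    known = {g.gene_id for g in genes}
    for gid in tss_table:
        if gid not in known:
            logger.warning("curated TSS for unknown gene id %r ignored", gid)
    out = []
    for g in genes:
        entry = tss_table.get(g.gene_id)
        if entry is None:
            out.append(g)
            continue
        if isinstance(entry, tuple):
            chrom, pos = entry
            if chrom != g.chrom:
                raise AnnotationError(
                    f"curated TSS for {g.gene_id} on {chrom}, gene on {g.chrom}")
        else:
            pos = int(entry)
        downstream_of_end = (pos >= g.end) if g.strand == "+" else (pos < g.start)
        if downstream_of_end:
            logger.warning(
                "curated TSS %d for %s lies downstream of gene end; ignored",
                pos, g.gene_id)
            out.append(g)
            continue
        out.append(replace(g, tss=pos, tss_source="curated"))
    return out


def _upstream_window(g: GeneRecord, window: int) -> tuple[int, int]:
    # Half-open genomic span of the `window` bases upstream of the TSS, in
    # the divergent direction.
    if g.strand == "+":
        return (g.tss - window, g.tss)
    return (g.tss + 1, g.tss + window + 1)


def classify_promoters(
    genes: Iterable[GeneRecord], window: int = 500
) -> list[PromoterClass]:
    """Label every gene tandem, divergent or overlapping.

    A gene is *overlapping* if its body intersects any other gene body on
    either strand; otherwise *divergent* if an opposite-strand gene's body or
    TSS intrudes into its upstream window (so the antisense quantification
    window could contain that gene's coding transcription); otherwise
    *tandem*. Divergent labelling is symmetric: both members of a pair are
    labelled, unless one of them is already overlapping.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    genes = _sorted_unique(genes)
    n = len(genes)
    label = {g.gene_id: "tandem" for g in genes}
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    overlapping: set[str] = set()
    for chrom_genes in by_chrom.values():
        for i in range(len(chrom_genes)):
            a = chrom_genes[i]
            for j in range(i + 1, len(chrom_genes)):
                b = chrom_genes[j]
                if b.start >= a.end:
                    break  # sorted by start; no later gene can overlap a
                overlapping.add(a.gene_id)
                overlapping.add(b.gene_id)
    for gid in overlapping:
        label[gid] = "overlapping"

    for chrom_genes in by_chrom.values():
        for g in chrom_genes:
            if label[g.gene_id] == "overlapping":
                continue
            lo, hi = _upstream_window(g, window)
            for h in chrom_genes:
                if h.gene_id == g.gene_id or h.strand == g.strand:
                    continue
                body_hits = h.start < hi and lo < h.end
                tss_hits = lo <= h.tss < hi
                if body_hits or tss_hits:
                    label[g.gene_id] = "divergent"
                    if label[h.gene_id] != "overlapping":
                        label[h.gene_id] = "divergent"
    out = [PromoterClass(g.gene_id, label[g.gene_id]) for g in genes]
    assert len(out) == n
    return out


def filter_noncoding_by_length(intervals, min_length: int = 200):
    """Keep intervals strictly longer than ``min_length`` bases.

    Accepts any sequence of objects with ``start``/``end`` attributes or
    (start, end, ...) tuples; order is preserved.
    """
    out = []
    for iv in intervals:
        if hasattr(iv, "start"):
            length = iv.end - iv.start
        else:
            length = iv[1] - iv[0]
        if length <= 0:
            raise ValueError(f"interval with non-positive length: {iv!r}")
        if length > min_length:
            out.append(iv)
    return out
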