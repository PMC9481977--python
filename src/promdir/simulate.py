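"""Synthetic stranded nascent-transcription data with known ground truth.

The generator emulates the statistical structure the directionality analysis
assumes: each promoter fires in the coding (sense) direction at rate
lambda_sense and in the divergent (antisense, upstream, short) direction at
rate lambda_antisense = lambda_sense / 10**delta, where delta is the true
per-promoter directionality on the log10 scale. Fragment 3'-end counts per
replicate are Poisson; sense ends fall uniformly in the first 500 bases of
the gene, divergent ends a geometric distance (mean ~150 bases, capped at
the 500-base window) upstream of the TSS on the opposite strand. A
"depleted" condition multiplies lambda_antisense by a factor m in a fraction
f of promoters. Spike-in genes receive counts unaffected by condition,
scaled only by per-sample depth distortions. A-track motifs are planted at a
fixed upstream offset with a probability that increases with delta, so
directional promoters are motif-enriched as in real promoter sequence.

Every output is a pure function of (params, seed); files are written in the
same formats the pipeline reads (FASTA, GFF3, BED6, bedGraph, TSV).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, write_annotation
from .coverage import StrandedCoverage, fragments_to_end_coverage, write_bedgraph
from .motifs import write_fasta

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "depleted")


@dataclass
class SimParams:
    """Generator configuration; defaults are the study conditions emulated.

    Rates are per replicate. ``sense_rate_mean`` is the arithmetic mean of
    the log-normal sense-rate distribution. ``directionality_mean/sd``
    parameterize the Normal truth delta (log10 units). The depleted
    condition multiplies the antisense rate by ``antisense_multiplier`` in a
    random ``affected_fraction`` of promoters.
    """

    seed: int = 0
    n_genes: int = 2000
    chrom: str = "chrI"
    chrom_length: int | None = None  # None: sized to fit the placement
    gene_length_range: tuple[int, int] = (500, 2000)
    spacing_range: tuple[int, int] = (600, 1200)  # guarantees tandem genes
    sense_rate_mean: float = 50.0
    sense_rate_sdlog: float = 0.3
    directionality_mean: float = 0.3
    directionality_sd: float = 0.8
    divergent_length_mean: float = 150.0
    window: int = 500
    affected_fraction: float = 0.25
    antisense_multiplier: float = 4.0
    n_replicates: int = 3
    n_spikein: int = 50
    spikein_rate_mean: float = 100.0
    spikein_rate_sdlog: float = 0.5
    fragment_length_range: tuple[int, int] = (80, 200)
    motif_pattern: str = "AAAAAAA"
    motif_offset: int = -100       # oriented offset of the planted motif start
    motif_prob_low: float = 0.1    # planting probability at low delta
    motif_prob_high: float = 0.6   # planting probability at high delta
    background_rate: float = 0.0   # per-base, per-strand noise rate

    def validate(self) -> None:
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.antisense_multiplier <= 0:
            raise ValueError("antisense_multiplier must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if min(self.sense_rate_mean, self.spikein_rate_mean) < 0:
            raise ValueError("rates must be non-negative")
        if self.spacing_range[0] <= self.window:
            raise ValueError(
                "minimum spacing must exceed the promoter window so that "
                "simulated genes classify as tandem")


def _rng(params: SimParams, *stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed & 0x7FFFFFFF, *stream])


def simulate_genome(
    params: SimParams,
) -> tuple[dict[str, str], list[GeneRecord], pd.DataFrame]:
    """Place genes on a uniform-random chromosome and draw per-gene truth.

    Genes are placed non-overlapping on random strands with intergenic
    spacing that keeps every promoter tandem. Returns (genome, genes, truth)
    where truth has one row per gene: rates, delta, affected flag and
    planted-motif bookkeeping.
    """
    params.validate()
    rng = _rng(params, 1)
    n = params.n_genes

    lengths = rng.integers(params.gene_length_range[0],
                           params.gene_length_range[1] + 1, n)
    spacings = rng.integers(params.spacing_range[0],
                            params.spacing_range[1] + 1, n)
    margin = params.window + 200
    starts = np.empty(n, dtype=int)
    cursor = margin
    for i in range(n):
        cursor += spacings[i]
        starts[i] = cursor
        cursor += lengths[i]
    needed = cursor + margin
    if params.chrom_length is not None and params.chrom_length < needed:
        raise ValueError(
            f"chrom_length {params.chrom_length} too short for {n} genes "
            f"(needs >= {needed}); reduce n_genes or gene/spacing ranges")
    chrom_len = params.chrom_length or needed

    strands = rng.choice(["+", "-"], size=n)
    mu = np.log(params.sense_rate_mean) - 0.5 * params.sense_rate_sdlog ** 2 \
        if params.sense_rate_mean > 0 else -np.inf
    lam_sense = (rng.lognormal(mu, params.sense_rate_sdlog, n)
                 if params.sense_rate_mean > 0 else np.zeros(n))
    delta = rng.normal(params.directionality_mean, params.directionality_sd, n)
    lam_anti = lam_sense / 10.0 ** delta
    affected = rng.random(n) < params.affected_fraction

    # motif planting probability rises with delta (logistic in delta)
    z = (delta - params.directionality_mean) / max(params.directionality_sd,
                                                   1e-9)
    p_plant = params.motif_prob_low + (
        params.motif_prob_high - params.motif_prob_low) / (1.0 + np.exp(-z))
    planted = rng.random(n) < p_plant

    seq = rng.choice(list("ACGT"), size=chrom_len)
    genes: list[GeneRecord] = []
    rows = []
    motif = params.motif_pattern.upper()
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(n):
        gid = f"gene_{i + 1:05d}"
        g = GeneRecord(chrom=params.chrom, start=int(starts[i]),
                       gene_id=gid, end=int(starts[i] + lengths[i]),
                       strand=str(strands[i]))
        genes.append(g)
        if planted[i]:
            off = params.motif_offset
            if g.strand == "+":
                lo = g.tss + off
                seq[lo:lo + len(motif)] = list(motif)
            else:
                # oriented offset p maps to genomic tss - p; write the
                # reverse complement so the coding-strand read is the motif
                hi = g.tss - off + 1
                seq[hi - len(motif):hi] = list(motif.translate(comp)[::-1])
        rows.append({
            "gene_id": gid, "chrom": g.chrom, "strand": g.strand,
            "tss": g.tss, "lambda_sense": float(lam_sense[i]),
            "delta": float(delta[i]),
            "lambda_antisense": float(lam_anti[i]),
            "affected": bool(affected[i]),
            "motif_planted": bool(planted[i]),
            "motif_offset": params.motif_offset if planted[i] else pd.NA,
        })
    genome = {params.chrom: "".join(seq)}
    truth = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "lambda_sense",
                       "delta", "lambda_antisense", "affected",
                       "motif_planted", "motif_offset"],
    ).set_index("gene_id")
    return genome, genes, truth


def simulate_coverage(
    params: SimParams,
    genes: Sequence[GeneRecord],
    truth: pd.DataFrame,
    condition: str,
    replicate: int,
) -> tuple[StrandedCoverage, list[tuple[str, int, int, str]]]:
    """One replicate of stranded fragment 3'-end coverage for a condition.

    Sense fragments end uniformly in the first ``window`` bases of the gene
    on the coding strand; divergent fragments end a truncated-geometric
    distance upstream on the opposite strand. Returns the coverage and the
    fragment list (transcript-strand BED-style tuples), which reproduce each
    other exactly through :func:`fragments_to_end_coverage`.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    params.validate()
    cond_code = CONDITIONS.index(condition)
    rng = _rng(params, 2, cond_code, replicate)
    frags: list[tuple[str, int, int, str]] = []
    w = params.window
    p_geom = 1.0 / params.divergent_length_mean
    fmin, fmax = params.fragment_length_range

    for g in genes:
        row = truth.loc[g.gene_id]
        lam_a = row["lambda_antisense"]
        if condition == "depleted" and row["affected"]:
            lam_a = lam_a * params.antisense_multiplier
        n_s = rng.poisson(row["lambda_sense"])
        n_a = rng.poisson(lam_a)
        t = g.tss
        if g.strand == "+":
            s_ends = rng.integers(t, t + w, n_s)           # 3' end positions
            # divergent 3' end at tss - (1 + geometric draw), clipped so it
            # stays inside the antisense window
            a_dist = np.minimum(rng.geometric(p_geom, n_a), w - 1)
            a_ends = t - 1 - a_dist
            s_strand, a_strand = "+", "-"
        else:
            s_ends = rng.integers(t - w + 1, t + 1, n_s)
            a_dist = np.minimum(rng.geometric(p_geom, n_a), w - 1)
            a_ends = t + 1 + a_dist
            s_strand, a_strand = "-", "+"
        lens_s = rng.integers(fmin, fmax + 1, n_s)
        lens_a = rng.integers(fmin, fmax + 1, n_a)
        for pos, L in zip(s_ends, lens_s):
            frags.append(_fragment(g.chrom, int(pos), int(L), s_strand))
        for pos, L in zip(a_ends, lens_a):
            frags.append(_fragment(g.chrom, int(pos), int(L), a_strand))

    chrom_len = max((g.end for g in genes), default=1000) + params.window + 200
    chrom = genes[0].chrom if genes else params.chrom
    chrom_sizes = {chrom: chrom_len}
    cov = fragments_to_end_coverage(
        frags, chrom_sizes, end_convention="3prime",
        library_strandness="forward",
        sample_id=f"{condition}_rep{replicate}")
    if params.background_rate > 0:
        for strand in ("+", "-"):
            noise = rng.poisson(params.background_rate, chrom_len)
            cov.data[chrom][strand] += noise
    return cov, frags


def _fragment(chrom: str, end3: int, length: int, strand: str):
    """Fragment interval whose 3'-most base on `strand` sits at end3."""
    if strand == "+":
        start, end = max(0, end3 - length + 1), end3 + 1
    else:
        start, end = end3, end3 + length
    return (chrom, start, end, strand)


def simulate_spikein_counts(
    params: SimParams,
    size_distortion: Mapping[str, float],
    truth: pd.DataFrame | None = None,
    global_shift: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample count matrix with spike-in rows.

    Spike-in counts are Poisson(rate * distortion_j): they track only the
    per-sample depth distortion, never the condition. When ``truth`` is
    given, main genes are included with counts Poisson(lambda_sense *
    distortion_j * global_shift_j), the global shift mimicking a genuine
    genome-wide change in transcription that internal normalization would
    hide. Returns (counts, spikein_flag).
    """
    params.validate()
    if any(d <= 0 for d in size_distortion.values()):
        raise ValueError("size distortions must be positive")
    rng = _rng(params, 3)
    samples = list(size_distortion)
    rates = rng.lognormal(
        np.log(params.spikein_rate_mean) - 0.5 * params.spikein_rate_sdlog ** 2,
        params.spikein_rate_sdlog, params.n_spikein)
    index = [f"spikein_{i + 1:03d}" for i in range(params.n_spikein)]
    blocks = {}
    for j, s in enumerate(samples):
        col = rng.poisson(rates * size_distortion[s])
        blocks[s] = col
    counts = pd.DataFrame(blocks, index=index)
    flags = pd.Series(True, index=index, name="spikein")
    if truth is not None:
        shift = {s: 1.0 for s in samples}
        if global_shift is not None:
            shift.update(global_shift)
        main = {}
        lam = truth["lambda_sense"].to_numpy()
        for s in samples:
            main[s] = rng.poisson(lam * size_distortion[s] * shift[s])
        main_df = pd.DataFrame(main, index=truth.index)
        counts = pd.concat([counts, main_df])
        flags = pd.concat([flags,
                           pd.Series(False, index=truth.index, name="spikein")])
    return counts, flags


def write_run(params: SimParams, outdir: str | Path,
              size_distortion: Mapping[str, float] | None = None) -> dict:
    """Generate a full synthetic study and write it under ``outdir``.

    Writes the genome FASTA, the GFF3 annotation, the truth table, per
    condition/replicate bedGraph pairs plus fragment BEDs, a spike-in count
    matrix, a sample sheet and a manifest listing every file with the seed.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_genome(params)
    files: dict[str, str] = {}

    write_fasta(genome, outdir / "genome.fa")
    files["genome"] = "genome.fa"
    write_annotation(genes, outdir / "genes.gff3", format="GFF3")
    files["annotation"] = "genes.gff3"
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    files["truth"] = "truth.tsv"

    chrom_sizes = {c: len(s) for c, s in genome.items()}
    with open(outdir / "chrom.sizes", "w") as fh:
        for c, n in chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")
    files["chrom_sizes"] = "chrom.sizes"

    sheet_rows = []
    for condition in CONDITIONS:
        for rep in range(1, params.n_replicates + 1):
            cov, frags = simulate_coverage(params, genes, truth, condition, rep)
            sample = f"{condition}_rep{rep}"
            plus = f"{sample}.plus.bedGraph"
            minus = f"{sample}.minus.bedGraph"
            write_bedgraph(cov, "+", outdir / plus)
            write_bedgraph(cov, "-", outdir / minus)
            bed = f"{sample}.fragments.bed"
            with open(outdir / bed, "w") as fh:
                for chrom, start, end, strand in frags:
                    fh.write(f"{chrom}\t{start}\t{end}\tfrag\t0\t{strand}\n")
            files[f"{sample}.plus"] = plus
            files[f"{sample}.minus"] = minus
            files[f"{sample}.fragments"] = bed
            sheet_rows.append({"sample_id": sample, "condition": condition,
                               "replicate": rep})
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    files["sample_sheet"] = "sample_sheet.tsv"

    if size_distortion is None:
        size_distortion = {r["sample_id"]: 1.0 for r in sheet_rows}
    counts, flags = simulate_spikein_counts(params, size_distortion, truth)
    counts_out = counts.copy()
    counts_out.insert(0, "spikein", flags.astype(int))
    counts_out.to_csv(outdir / "counts.tsv", sep="\t",
                      index_label="gene_id")
    files["counts"] = "counts.tsv"

    manifest = {
        "seed": params.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(params).items()},
        "library_strandness": "forward",  # fragments carry transcript strand
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("wrote synthetic run with %d genes to %s",
                params.n_genes, outdir)
    return manifest
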