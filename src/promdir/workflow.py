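"""End-to-end orchestration: config validation and the score/motifs/metagene
pipelines over files on disk.

A run is described by a YAML config (paths, parameters, sample sheet). Every
pipeline writes deterministic, headered TSVs and logs the record count
surviving each filtering step, since those counts are the analysis's main
checkable intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import coverage as cvg
from . import directionality as dirn
from . import metagene as mg
from . import motifs as mot

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Validation failure; message lists every violation found."""


@dataclass
class RunConfig:
    annotation: str = ""
    annotation_format: str = "GFF3"
    genome: str = ""
    chrom_sizes: str = ""
    counts: str = ""
    coverage: dict = field(default_factory=dict)  # sample_id -> {plus, minus}
    sample_sheet: list = field(default_factory=list)
    window: int = 500
    pseudocount: float = 1.0
    flank: int = 500
    end_convention: str = "3prime"
    library_strandness: str = "reverse"
    quintile_count: int = 5
    motif_list: list = field(default_factory=lambda: [
        {"name": "A-track", "pattern": "AAAAAAA", "scan_strand": "sense"},
        {"name": "CG(C/G)G", "pattern": "CG[CG]G", "scan_strand": "sense"},
    ])
    reference_condition: str = "control"
    treated_condition: str = "depleted"
    track: str = ""  # bedGraph track for the metagene step
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, require: tuple[str, ...] = ()) -> None:
        """Collect every violation and raise once, naming all of them."""
        problems: list[str] = []
        for name in require:
            if name in ("coverage", "sample_sheet"):
                continue  # structured fields, checked below
            path = getattr(self, name, "")
            if not path:
                problems.append(f"missing required field: {name}")
            elif not Path(path).exists():
                problems.append(f"{name} file not found: {path}")
        if "coverage" in require:
            if not self.coverage:
                problems.append("missing required field: coverage")
            for sample, pair in self.coverage.items():
                for key in ("plus", "minus"):
                    if key not in pair:
                        problems.append(
                            f"coverage[{sample}] missing {key} bedGraph")
                    elif not Path(pair[key]).exists():
                        problems.append(
                            f"coverage[{sample}].{key} not found: {pair[key]}")
        if "sample_sheet" in require:
            if not self.sample_sheet:
                problems.append("sample sheet is empty")
            for row in self.sample_sheet:
                for key in ("sample_id", "condition", "replicate"):
                    if key not in row:
                        problems.append(f"sample sheet row missing {key}: {row}")
        if self.window <= 0:
            problems.append("window must be positive")
        if self.end_convention not in cvg.END_CONVENTIONS:
            problems.append(f"end_convention must be one of "
                            f"{sorted(cvg.END_CONVENTIONS)}")
        if self.library_strandness not in cvg.STRANDNESS:
            problems.append(f"library_strandness must be one of "
                            f"{sorted(cvg.STRANDNESS)}")
        if self.quintile_count != 5:
            problems.append("quintile_count is fixed at 5")
        if problems:
            raise ConfigError("; ".join(problems))

    def sheet(self) -> pd.DataFrame:
        return pd.DataFrame(self.sample_sheet)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def load_tandem_genes(config: RunConfig) -> list[ann.GeneRecord]:
    """Annotation -> promoter classes -> the tandem gene set, with logging."""
    genes = ann.read_annotation(config.annotation, config.annotation_format)
    logger.info("annotation: %d genes", len(genes))
    classes = ann.classify_promoters(genes, window=config.window)
    keep = {c.gene_id for c in classes if c.label == "tandem"}
    tandem = [g for g in genes if g.gene_id in keep]
    logger.info("tandem non-overlapping genes: %d of %d",
                len(tandem), len(genes))
    return tandem


def run_score(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Windows -> directionality per condition -> changes -> quintiles.

    Writes window_counts.tsv, directionality_<condition>.tsv, changes.tsv
    and quintiles.tsv under the configured output directory and returns the
    tables keyed by name.
    """
    config.validate(require=("annotation", "chrom_sizes", "coverage",
                             "sample_sheet"))
    sheet = config.sheet()
    missing = set(sheet["sample_id"]) - set(config.coverage)
    if missing:
        raise ConfigError(
            f"sample sheet entries without coverage files: {sorted(missing)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    tandem = load_tandem_genes(config)
    if not tandem:
        logger.warning("no tandem genes survive filtering; tables are empty")

    rows = []
    for sample in sheet["sample_id"]:
        pair = config.coverage[sample]
        cov = cvg.read_bedgraph_pair(pair["plus"], pair["minus"], chrom_sizes,
                                     sample_id=sample)
        for wc in cvg.count_promoter_windows(tandem, cov,
                                             window=config.window):
            rows.append({"gene_id": wc.gene_id, "sample_id": sample,
                         "sense": wc.sense_count,
                         "antisense": wc.antisense_count,
                         "clipped": int(wc.clipped)})
    window_counts = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "sense", "antisense",
                       "clipped"])
    window_counts.to_csv(outdir / "window_counts.tsv", sep="\t", index=False)

    tables: dict[str, pd.DataFrame] = {"window_counts": window_counts}
    per_condition = {}
    for condition in sheet["condition"].unique():
        if len(window_counts) == 0:
            table = pd.DataFrame(columns=["S", "A", "replicate_count", "D"])
        else:
            table = dirn.directionality_table(
                window_counts, sheet, condition,
                pseudocount=config.pseudocount)
        per_condition[condition] = table
        table.to_csv(outdir / f"directionality_{condition}.tsv", sep="\t",
                     index_label="gene_id")
        tables[f"directionality_{condition}"] = table
        logger.info("directionality (%s): %d genes", condition, len(table))

    ref, trt = config.reference_condition, config.treated_condition
    if ref in per_condition and trt in per_condition \
            and len(per_condition[ref]) and len(per_condition[trt]):
        changes = dirn.change_table(per_condition[trt], per_condition[ref],
                                    label_t=trt, label_c=ref)
        changes.to_csv(outdir / "changes.tsv", sep="\t",
                       index_label="gene_id")
        tables["changes"] = changes
        quint = dirn.stratify_quintiles(per_condition[ref]["D"])
        qtable = quint.labels.to_frame()
        qtable["D"] = per_condition[ref]["D"]
        qtable.sort_index().to_csv(outdir / "quintiles.tsv", sep="\t",
                                   index_label="gene_id")
        quint.summary.to_csv(outdir / "quintile_summary.tsv", sep="\t",
                             index=False)
        tables["quintiles"] = qtable
        tables["quintile_summary"] = quint.summary
    return tables


def run_motifs(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Quintile-stratified motif profiles and Q1-vs-Q5 enrichment.

    Requires quintiles.tsv from a previous score run in the output
    directory (or runs on all tandem genes as a single group when absent).
    """
    config.validate(require=("annotation", "genome"))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = mot.read_fasta(config.genome)
    tandem = load_tandem_genes(config)
    by_id = {g.gene_id: g for g in tandem}

    qpath = outdir / "quintiles.tsv"
    groups: dict[str, list[ann.GeneRecord]]
    if qpath.exists():
        qtab = pd.read_csv(qpath, sep="\t", index_col="gene_id")
        groups = {
            q: [by_id[g] for g in qtab.index[qtab["quintile"] == q]
                if g in by_id]
            for q in dirn.QUINTILE_LABELS
        }
    else:
        groups = {"all": tandem}

    motifs = [mot.MotifSpec(m["name"], m["pattern"],
                            m.get("scan_strand", "sense"))
              for m in config.motif_list]
    profile_rows = []
    for m in motifs:
        for gname, genes in groups.items():
            if not genes:
                raise ConfigError(f"promoter group {gname!r} is empty")
            prof = mot.motif_profile(genes, genome, m, flank=config.flank,
                                     group=gname)
            for off, frac in zip(prof.offsets, prof.fraction):
                profile_rows.append({
                    "motif": m.name, "scan_strand": m.scan_strand,
                    "group": gname, "offset": int(off),
                    "fraction": float(frac)})
    profiles = pd.DataFrame(profile_rows)
    profiles.to_csv(outdir / "motif_profiles.tsv", sep="\t", index=False)

    enrich_rows = []
    if "Q5" in groups and "Q1" in groups:
        for m in motifs:
            res = mot.motif_enrichment(groups["Q5"], groups["Q1"], genome, m,
                                       flank=config.flank)
            enrich_rows.append({
                "motif": m.name, "scan_strand": m.scan_strand,
                "group_a": "Q5", "group_b": "Q1",
                "fold_enrichment": res.fold_enrichment,
                "p_value": res.p_value, "higher_group": res.higher_group,
                "mean_a": res.mean_a, "mean_b": res.mean_b})
    enrichment = pd.DataFrame(enrich_rows)
    enrichment.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    return {"profiles": profiles, "enrichment": enrichment}


def run_metagene(config: RunConfig) -> dict[str, pd.DataFrame]:
    """TSS-centred matrix and mean profile of a normalized per-base track."""
    config.validate(require=("annotation", "chrom_sizes", "track"))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    raw = cvg.read_bedgraph(config.track, chrom_sizes, "+")
    track = {c: raw.data[c]["+"] for c in raw.data}
    norm = mg.normalize_track(track)
    tandem = load_tandem_genes(config)

    qpath = outdir / "quintiles.tsv"
    by_id = {g.gene_id: g for g in tandem}
    if qpath.exists():
        qtab = pd.read_csv(qpath, sep="\t", index_col="gene_id")
        groups = {
            q: [by_id[g] for g in qtab.index[qtab["quintile"] == q]
                if g in by_id]
            for q in dirn.QUINTILE_LABELS
        }
    else:
        groups = {"all": tandem}

    out: dict[str, pd.DataFrame] = {}
    profile_rows = []
    for gname, genes in groups.items():
        if not genes:
            raise ConfigError(f"promoter group {gname!r} is empty")
        matrix = mg.matrix_at_tss(genes, norm, upstream=config.flank,
                                  downstream=config.flank)
        matrix.to_csv(outdir / f"metagene_matrix_{gname}.tsv", sep="\t",
                      index_label="gene_id")
        means, n = mg.mean_profile(matrix)
        for off in matrix.columns:
            profile_rows.append({"group": gname, "offset": int(off),
                                 "mean_signal": float(means[off]),
                                 "n": int(n[off])})
        out[f"matrix_{gname}"] = matrix
    profiles = pd.DataFrame(profile_rows)
    profiles.to_csv(outdir / "metagene_profiles.tsv", sep="\t", index=False)
    out["profiles"] = profiles
    return out
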