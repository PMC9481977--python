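"""Shared paths and config assembly for the numbered analysis scripts.

The synthetic study (genome, coverage, counts) lives under scratch/ — it is
large and fully regenerable from the seed. The compact tables each script
derives from it are written under results/.
"""

from pathlib import Path

import pandas as pd

from promdir.workflow import RunConfig

ROOT = Path(__file__).resolve().parent.parent
SIMDIR = ROOT / "scratch" / "simdata"
SCOREDIR = ROOT / "scratch" / "scored"
RESULTS = ROOT / "results"

SEED = 1


def study_config() -> RunConfig:
    """RunConfig pointing at the simulated study written by 01_simulate.py."""
    sheet = pd.read_csv(SIMDIR / "sample_sheet.tsv", sep="\t")
    coverage = {
        r.sample_id: {
            "plus": str(SIMDIR / f"{r.sample_id}.plus.bedGraph"),
            "minus": str(SIMDIR / f"{r.sample_id}.minus.bedGraph"),
        }
        for r in sheet.itertuples()
    }
    return RunConfig(
        annotation=str(SIMDIR / "genes.gff3"),
        genome=str(SIMDIR / "genome.fa"),
        chrom_sizes=str(SIMDIR / "chrom.sizes"),
        counts=str(SIMDIR / "counts.tsv"),
        coverage=coverage,
        sample_sheet=sheet.to_dict("records"),
        library_strandness="forward",  # simulator fragments carry transcript strand
        track=coverage["control_rep1"]["plus"],
        outdir=str(SCOREDIR),
    )
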