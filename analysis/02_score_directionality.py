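"""Score promoter directionality and stratify promoters into quintiles.

Runs the full scoring pipeline on the simulated study: bedGraph pairs ->
promoter window counts -> per-condition directionality tables ->
condition changes -> quintiles on the control-condition score. Per-gene
tables land under scratch/scored; this script summarises them into two
result tables: the quintile score ranges and the per-quintile mean changes
in divergent transcription, sense transcription and directionality (the
violin-plot-style readout of which promoter class responds most).
"""

import pandas as pd

from common import RESULTS, SCOREDIR, study_config
from promdir.workflow import run_score


def main() -> None:
    config = study_config()
    tables = run_score(config)

    qsummary = tables["quintile_summary"]
    qsummary.to_csv(RESULTS / "02_quintile_summary.tsv", sep="\t",
                    index=False)

    changes = tables["changes"].join(tables["quintiles"]["quintile"])
    per_q = changes.groupby("quintile")[
        ["log2FC_divergent", "log2FC_sense", "delta_directionality"]
    ].mean().round(4)
    per_q["n"] = changes.groupby("quintile").size()
    per_q.to_csv(RESULTS / "02_quintile_changes.tsv", sep="\t")

    print("quintile score ranges (control condition):")
    print(qsummary.to_string(index=False))
    print("\nmean change per quintile (depleted vs control):")
    print(per_q.to_string())
    print(f"\nper-gene tables under {SCOREDIR}")


if __name__ == "__main__":
    main()
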