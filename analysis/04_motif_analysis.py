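"""Strand-aware motif profiles and Q5-vs-Q1 enrichment on the simulated study.

The generator plants A-tracks at oriented offset -100 with a probability
that rises with true directionality, so the profile for the most
directional quintile (Q5) should peak at -100 and the A-track should be
enriched in Q5 over Q1. Writes the per-group profile peaks and the
enrichment statistics under results/.
"""

import pandas as pd

from common import RESULTS, study_config
from promdir.workflow import run_motifs


def main() -> None:
    config = study_config()
    out = run_motifs(config)

    profiles = out["profiles"]
    peaks = (profiles.loc[profiles.groupby(["motif", "group"])
                          ["fraction"].idxmax()]
             [["motif", "group", "offset", "fraction"]]
             .rename(columns={"offset": "peak_offset",
                              "fraction": "peak_fraction"}))
    peaks["peak_fraction"] = peaks["peak_fraction"].round(4)
    peaks.to_csv(RESULTS / "04_motif_profile_peaks.tsv", sep="\t",
                 index=False)

    enrichment = out["enrichment"].copy()
    enrichment.to_csv(RESULTS / "04_motif_enrichment.tsv", sep="\t",
                      index=False)

    print("profile peaks per quintile:")
    print(peaks.to_string(index=False))
    print("\nQ5 vs Q1 enrichment:")
    print(enrichment.to_string(index=False))


if __name__ == "__main__":
    main()
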