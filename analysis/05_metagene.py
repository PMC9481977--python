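"""TSS-centred metagene profiles of the normalized coverage track.

Uses the plus-strand coverage of one control replicate as the per-base
track, normalizes it over its total signal (log2), and builds
quintile-stratified, strand-oriented matrices around the TSS. Directional
promoters (Q5) should show strong sense-direction signal downstream of the
TSS relative to upstream; Q1 promoters should not. Writes per-group
upstream/downstream mean signal under results/.
"""

import pandas as pd

from common import RESULTS, study_config
from promdir.workflow import run_metagene


def main() -> None:
    config = study_config()
    out = run_metagene(config)
    prof = out["profiles"]

    rows = []
    for group, sub in prof.groupby("group"):
        up = sub.loc[sub["offset"] < 0, "mean_signal"].mean()
        down = sub.loc[sub["offset"] >= 0, "mean_signal"].mean()
        rows.append({"group": group,
                     "mean_signal_upstream": round(up, 4),
                     "mean_signal_downstream": round(down, 4),
                     "downstream_minus_upstream": round(down - up, 4)})
    summary = pd.DataFrame(rows).sort_values("group")
    summary.to_csv(RESULTS / "05_metagene_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
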