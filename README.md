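# promdir

Promoter directionality analysis from strand-specific nascent-transcription
3′-end coverage.

Active gene promoters fire in two directions: the coding (sense) direction,
and a divergent noncoding direction producing short upstream transcripts on
the opposite strand. How strongly a promoter favours its coding direction —
and how that balance shifts when chromatin remodellers or general
regulatory factors are perturbed — is captured by the **promoter
directionality score**

    D = log10(S / A)

with `S` the nascent signal in +1..+500 downstream of the TSS on the coding
strand and `A` the signal in −1..−500 upstream on the opposite strand, each
a replicate mean of pseudocounted window counts. `promdir` is for
epigenomics/regulatory-genomics analysts who have stranded 3′-end coverage
(bedGraph pairs or fragment BED), a gene annotation, and optionally a
genome FASTA and spike-in counts, and who want:

- tandem promoter curation (overlapping and divergent gene pairs removed so
  the antisense window never contains a neighbour's coding transcription);
- per-promoter directionality scores and condition-wise changes
  (`log2FC_divergent`, `log2FC_sense`, `Δdirectionality` on the log2
  scale), with spike-in median-of-ratios size factors;
- quintile stratification (Q1 lowest → Q5 highest directionality);
- strand-aware A-track / `CG[CG]G` motif profiles and group enrichment;
- TSS-centred, strand-oriented metagene matrices of per-base tracks;
- a ground-truth synthetic-data generator for validating all of the above.

## Worked example

Generate a synthetic study (2,000 tandem promoters, 3 replicates ×
{control, depleted}, the depleted condition multiplying the antisense rate
by 4 in 25% of promoters), then score it:

```python
import pandas as pd
from promdir.simulate import SimParams, simulate_genome, simulate_coverage
from promdir.coverage import count_promoter_windows
from promdir.directionality import directionality_table, change_table

params = SimParams(seed=1)
genome, genes, truth = simulate_genome(params)

rows, sheet = [], []
for cond in ("control", "depleted"):
    for rep in (1, 2, 3):
        cov, _ = simulate_coverage(params, genes, truth, cond, rep)
        sid = f"{cond}_rep{rep}"
        sheet.append({"sample_id": sid, "condition": cond, "replicate": rep})
        rows += [{"gene_id": w.gene_id, "sample_id": sid,
                  "sense": w.sense_count, "antisense": w.antisense_count}
                 for w in count_promoter_windows(genes, cov)]
wc, sheet = pd.DataFrame(rows), pd.DataFrame(sheet)

ctrl = directionality_table(wc, sheet, "control")
depl = directionality_table(wc, sheet, "depleted")
print(change_table(depl, ctrl).loc[truth.index[truth.affected],
      ["log2FC_divergent", "delta_directionality"]].mean().round(3))
```

prints

```
log2FC_divergent        1.839
delta_directionality   -1.832
```

— the affected promoters' divergent transcription rises by close to the
simulated 4-fold (log2 4 = 2; the pseudocount pulls the estimate slightly
toward zero), and their directionality drops by the same amount on the
log2 scale, while sense transcription is unchanged.

The same analysis as a shell workflow:

```
promdir simulate --seed 1 --n-genes 2000 --outdir run/
promdir score  --config config.yaml     # windows -> scores -> quintiles
promdir motifs --config config.yaml     # profiles + Q5-vs-Q1 enrichment
promdir metagene --config config.yaml   # TSS-centred matrices
```

The numbered scripts under `analysis/` run the complete study end to end
(`01_simulate.py` … `05_metagene.py`), writing the simulated data under
`scratch/` and compact summary tables under `results/`.

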