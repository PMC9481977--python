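# Methods

## The quantity being estimated

Active gene promoters fire in two directions: the coding (sense) direction
and a divergent noncoding (antisense) direction that initiates from the same
nucleosome-depleted region and produces short upstream transcripts on the
opposite strand. `promdir` quantifies both from strand-specific nascent
transcription data and summarises each promoter by a **directionality
score**

    D = log10(S / A)

where `S` is the signal in the window +1..+500 downstream of the TSS on the
coding strand, `A` the signal in −1..−500 upstream on the opposite strand,
each a mean over biological replicates of pseudocounted window counts
(below). `D > 0` means the promoter fires predominantly in the coding
direction; highly directional yeast promoters reach `D` of 3–4 in deep
nascent RNA-seq data.

## Signal model and counting conventions

Each sequenced fragment is reduced to a single nucleotide — by default its
3′-terminal base on the transcript strand — and accumulated into dense
per-chromosome, per-strand vectors. Both 3′ and 5′ end conventions are
supported (`end_convention`); the default is 3′, and the choice is exposed
rather than hidden because published pipelines are not always consistent
about which end their coverage command actually kept. Library strandness
(`forward`/`reverse`) governs the mapping from a fragment's recorded
orientation to the transcript strand; `reverse` is the default, matching
dUTP-based stranded protocols, and the simulator, which emits
transcript-strand fragments, always sets `forward` in its manifests.

Coordinates are 0-based half-open throughout; GFF3 input is converted at
parse time. For a plus-strand gene with TSS `t`, the sense window is
`[t, t+500)` on `+` and the antisense window `[t−500, t)` on `−`; the
minus-strand case mirrors this exactly (`[t−499, t+1)` on `−`;
`[t+1, t+501)` on `+`). Windows overhanging a chromosome edge are truncated
and flagged, not dropped.

### Pseudocount placement

A pseudocount of 1 is added to **each replicate count before averaging**:
`S = mean_r(sense_r + 1)`. The alternative (average first, then add 1)
differs at low counts; the add-first order is the one this package defines
and tests. Consequences: `S, A ≥ 1`, `D` is always finite, and `D` is
biased toward 0 whenever the true rate in either direction is of order 1 —
an estimator property to keep in mind at low sequencing depth.

### Tandem promoter filtering

The score is only meaningful where upstream antisense signal can be
attributed to divergent *noncoding* initiation. Promoters are therefore
classified before scoring:

- **overlapping** — the gene body intersects any other gene body, either
  strand;
- **divergent** — an opposite-strand gene's body or TSS intrudes into the
  500-bp upstream window (the same length as the antisense quantification
  window, so by construction the antisense window of a surviving gene can
  never contain a neighbour's coding transcription); the label is applied
  symmetrically to both members of a pair;
- **tandem** — everything else. Only tandem promoters are scored.

## Condition comparisons

Changes between conditions are plain ratios of size-factor-normalized,
pseudocounted replicate means — no shrinkage, no dispersion model:

    log2FC_divergent = log2(Ã_t / Ã_c),   log2FC_sense = log2(S̃_t / S̃_c)

and the directionality change is reported on the log2 scale through the
exact conversion `delta = (D_t − D_c)·log2(10)`, which equals
`log2FC_sense − log2FC_divergent` whenever all four quantities come from
the same pseudocounted means. Differential-expression machinery with
shrunken fold changes and adjusted p-values is deliberately out of scope;
this package reports effect sizes, not significance calls, for per-gene
changes.

### Spike-in size factors

When a global shift in transcription is possible (e.g., depleting a factor
that affects RNA polymerase activity genome-wide), internal normalization
hides it. Size factors are therefore computed by median-of-ratios
restricted to spike-in genes: for sample `j`,
`sf_j = median_i( c_ij / geomean_j'(c_ij') )` over spike-in genes `i` with
nonzero counts in every sample. The estimator is scale-equivariant across
samples and invariant to gene order; it requires at least one all-nonzero
spike-in gene.

### Quintile stratification

Promoters are split into five equal-count groups (Q1 lowest … Q5 highest)
by stable sort on (score, gene_id); when the count is not divisible by 5
the larger groups sit at the low end, and ties are broken by gene id, so
the assignment is a pure function of the score table.

## Motif analysis

Motifs are short patterns with single-position alternatives (A-track
`AAAAAAA`; GC motif `CG[CG]G`). Scanning reports **every** match start,
overlapping occurrences included — this matters for homopolymer runs, where
an 8-mer A-run contains two A7 starts; a presence/absence or
non-overlapping convention would give systematically different A-track
statistics, so the convention is stated here and enforced by tests against
a naive sliding-window oracle. `N` never matches. Antisense scanning scans
the reverse complement and maps matches back to the leftmost base of the
footprint.

Promoter sequences are extracted ±flank around the TSS and oriented so the
coding strand reads left-to-right before scanning; profiles report, per
TSS-relative offset, the fraction of promoters with a match starting there.
Group enrichment compares per-promoter match counts between two groups:
fold enrichment is the ratio of group means with 0.5 added to each mean,
and the p-value is a two-sided Mann–Whitney rank-sum test. Promoters whose
window overhangs a chromosome end are skipped and logged, not padded.

## Metagene matrices

Per-base tracks are normalized over their own total signal and
log2-transformed (`log2(v/total + 1e−6)`), making tracks of different depth
comparable. The TSS-centred matrix has one row per gene and one column per
offset at bin size 1; rows of minus-strand genes are orientation-flipped so
transcription runs left-to-right. Missing data (off-chromosome positions)
is kept as NaN, distinct from zero signal, end-to-end; `skip_zeros` drops
and logs all-zero rows. Mean profiles ignore missing values and report
per-offset n.

## The synthetic-data generator

The generator produces the full file set the pipeline consumes (FASTA,
GFF3, BED6 fragments, bedGraph pairs, count matrix with spike-in flags,
sample sheet, manifest) so tests exercise the real I/O paths. Its
statistical structure:

- genes placed non-overlapping on random strands with intergenic spacing
  drawn from U(600, 1200) — always wider than the 500-bp window, so every
  simulated promoter classifies tandem;
- per-promoter sense rate λ_s ~ lognormal with arithmetic mean **50
  fragments/promoter/replicate** (sdlog 0.3);
- true directionality δ ~ Normal(**0.3**, **0.8**) in log10 units, with
  λ_a = λ_s/10^δ;
- per replicate, sense 3′ ends are Poisson(λ_s) placed uniformly in
  `[TSS, TSS+500)` on the coding strand; divergent 3′ ends are Poisson(λ_a)
  at `TSS − (1 + G)` on the opposite strand, G geometric with mean 150,
  clipped at the window edge — emulating the short length of divergent
  transcription units;
- the depleted condition multiplies λ_a by **4** in a random **25%** of
  promoters; replicates (3 per condition) are independent streams;
- spike-in genes (50) get Poisson counts scaled only by per-sample depth
  distortions, never by condition;
- A-tracks are planted at oriented offset −100 with probability rising
  logistically in δ from 0.1 to 0.6, so directional promoters are
  motif-enriched.

### Why the truth directionality is centred near zero

Real yeast nascent RNA-seq reaches thousands of fragments per promoter, and
observed directionality scores centre near 2 (sense ~100× antisense). At
the desk-scale depth this generator targets (mean 50 sense fragments), a
promoter with δ = 2 would have λ_a = 0.5: its antisense estimate would be
dominated by the pseudocount and neither the score nor a 4× antisense
change would be measurable by *any* estimator. The generator therefore
models a weaker-directionality regime — δ ~ N(0.3, 0.8), putting typical
antisense rates in the tens — which preserves every qualitative feature of
the real data (both directions active, antisense shorter and weaker on
average, directionality widely spread) while keeping the recovery problem
well-posed at this depth. Recovery results on the synthetic data
demonstrate that the estimators are consistent and unbiased where the data
can support them; they do not certify performance at the pseudocount-
dominated extreme of real highly-directional promoters.

What the generator does **not** model: overdispersion beyond Poisson,
background/antisense leakage outside promoter windows (available as an
optional uniform background rate, default 0), sequence-dependent initiation
preferences, fragment-length biases, and multi-isoform TSS heterogeneity.
Passing recovery tests therefore show correctness of the estimators under
the stated sampling model, not robustness to every artefact of real
libraries.

## Numerical and design choices

- Dense per-base vectors (float64) rather than sparse structures: target
  genomes are megabase-scale, and dense sums are bit-exact and branch-free.
- bedGraph writing run-length-encodes and omits zero runs; reading rejects
  overlapping or unsorted intervals rather than silently summing them.
- All tabular outputs have headers and deterministic row order
  (sorted by gene id or by (chrom, start, gene_id)).
- Curated TSSs take precedence over annotation-derived ones; a curated
  position downstream of the gene end is ignored with a warning, a
  chromosome mismatch is an error.
- Noncoding-transcript length filtering keeps intervals strictly longer
  than the threshold (length > 200, not ≥).
- Quintile remainders go to the low-score groups; group sizes differ by at
  most one.
- Degenerate inputs: zero replicates, empty promoter groups, zero-total
  tracks, and sub-5-gene quintile requests raise errors; all-zero
  enrichment comparisons return fold 1.0, p 1.0.
- Seeds: every generator output is a pure function of (params, seed);
  replicate/condition streams are derived sub-streams, so adding a
  replicate never perturbs existing ones.

## Problem sizes

Default study conditions are 2,000 promoters, 3 replicates × 2 conditions
at mean sense depth 50 — chosen as the smallest configuration at which
quintile membership is stable run-to-run and recovery metrics have
comfortable margins; the full pipeline runs in seconds on one core.

## Known limitations

- The promoter classifier uses gene bodies as annotated; UTR extensions or
  isoform-specific ends would change the tandem set.
- Fold-change estimates are unshrunken; at very low counts they are noisy
  and pseudocount-biased toward zero.
- The enrichment test treats promoters as exchangeable; GC content or
  length confounds between groups are not modelled.
- Only one TSS per gene is carried; alternative TSS usage is out of scope.
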