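"""Directionality scores, spike-in size factors, condition changes, quintiles.

The promoter directionality score of a gene is D = log10(S/A), where S and A
are the pseudocounted replicate means of the sense and antisense promoter
window counts. A pseudocount is added to every replicate count *before*
averaging, so S, A >= 1 and D is always finite; D > 0 means the promoter
fires predominantly in the coding direction.

Condition-wise changes are plain ratios of normalized, pseudocounted means
(no shrinkage): log2FC of the divergent and sense signals, and the
directionality change expressed on the log2 scale via the exact conversion
delta = (D_t - D_c) * log2(10), which equals log2FC_sense - log2FC_divergent
when all quantities are computed from the same pseudocounted means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOG2_10 = math.log2(10.0)

QUINTILE_LABELS = ["Q1", "Q2", "Q3", "Q4", "Q5"]


def pseudocounted_mean(reps: Sequence[float], pseudocount: float = 1.0) -> float:
    """Mean over replicates of (count + pseudocount)."""
    arr = np.asarray(list(reps), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one replicate is required")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float((arr + pseudocount).mean())


def directionality_score(
    sense_reps: Sequence[float],
    antisense_reps: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """D = log10(S/A) with S, A the pseudocounted replicate means."""
    s = list(sense_reps)
    a = list(antisense_reps)
    if len(s) != len(a):
        raise ValueError("sense and antisense replicate counts must match")
    S = pseudocounted_mean(s, pseudocount)
    A = pseudocounted_mean(a, pseudocount)
    return math.log10(S / A)


@dataclass
class SizeFactors:
    factors: pd.Series  # per sample, positive
    spikein_used: list[str]


def spikein_size_factors(
    count_matrix: pd.DataFrame,
    spikein_ids: Iterable[str],
) -> SizeFactors:
    """Median-of-ratios size factors restricted to spike-in genes.

    For sample j, sf_j = median over spike-in genes i (nonzero in every
    sample) of count_ij / geometric-mean-over-samples(count_i.). Gene order
    does not matter; at least one spike-in gene must be nonzero in all
    samples.
    """
    ids = [g for g in spikein_ids if g in count_matrix.index]
    sub = count_matrix.loc[ids].astype(float)
    if (sub < 0).any().any():
        raise ValueError("counts must be non-negative")
    usable = sub.index[(sub > 0).all(axis=1)]
    if len(usable) == 0:
        raise ValueError(
            "no spike-in gene has nonzero counts in all samples")
    sub = sub.loc[usable]
    log_geo = np.log(sub).mean(axis=1)
    ratios = sub.div(np.exp(log_geo), axis=0)
    factors = ratios.median(axis=0)
    return SizeFactors(factors=factors, spikein_used=list(usable))


def log2fc(
    count_t: float,
    count_c: float,
    sf_t: float = 1.0,
    sf_c: float = 1.0,
    pseudocount: float = 1.0,
) -> float:
    """log2 of the ratio of size-factor-normalized, pseudocounted counts."""
    if count_t < 0 or count_c < 0:
        raise ValueError("counts must be non-negative")
    if sf_t <= 0 or sf_c <= 0:
        raise ValueError("size factors must be positive")
    return math.log2((count_t / sf_t + pseudocount)
                     / (count_c / sf_c + pseudocount))


def directionality_change(D_t: float, D_c: float) -> float:
    """Directionality change on the log2 scale: (D_t - D_c) * log2(10)."""
    return (D_t - D_c) * LOG2_10


@dataclass
class QuintileAssignment:
    labels: pd.Series       # gene_id -> Q1..Q5
    summary: pd.DataFrame   # per quintile: min_score, max_score, size


def stratify_quintiles(scores: pd.Series) -> QuintileAssignment:
    """Split genes into five equal-count groups by ascending score.

    Stable sort by (score, gene_id); group sizes differ by at most one with
    the larger groups at the low end; Q1 holds the lowest scores and Q5 the
    highest. Ties are resolved deterministically by gene_id.
    """
    scores = scores.astype(float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(scores) < 5:
        raise ValueError("at least 5 genes are required for quintiles")
    order = sorted(scores.index, key=lambda gid: (scores[gid], str(gid)))
    chunks = np.array_split(np.array(order, dtype=object), 5)
    labels = {}
    rows = []
    for lab, chunk in zip(QUINTILE_LABELS, chunks):
        vals = scores[list(chunk)]
        rows.append({"quintile": lab, "min_score": float(vals.min()),
                     "max_score": float(vals.max()), "size": len(chunk)})
        for gid in chunk:
            labels[gid] = lab
    label_series = pd.Series({gid: labels[gid] for gid in scores.index},
                             name="quintile")
    return QuintileAssignment(labels=label_series,
                              summary=pd.DataFrame(rows))


def directionality_table(
    window_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    condition: str,
    pseudocount: float = 1.0,
    size_factors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene S, A and D for one condition.

    ``window_counts`` is long-form (gene_id, sample_id, sense, antisense);
    ``sample_sheet`` maps sample_id to (condition, replicate). Counts are
    divided by the sample's size factor (if given) before pseudocounting,
    then averaged over the condition's replicates.
    """
    samples = sample_sheet.loc[sample_sheet["condition"] == condition,
                               "sample_id"]
    if len(samples) == 0:
        raise ValueError(f"no samples for condition {condition!r}")
    sub = window_counts[window_counts["sample_id"].isin(samples)].copy()
    missing = set(samples) - set(sub["sample_id"])
    if missing:
        raise ValueError(f"no window counts for samples {sorted(missing)}")
    sf = pd.Series({s: 1.0 for s in samples}, dtype=float)
    if size_factors is not None:
        for s in samples:
            sf[s] = float(size_factors[s])
    sub["sense_n"] = sub["sense"] / sub["sample_id"].map(sf) + pseudocount
    sub["antisense_n"] = (sub["antisense"] / sub["sample_id"].map(sf)
                          + pseudocount)
    agg = sub.groupby("gene_id")[["sense_n", "antisense_n"]].mean()
    table = pd.DataFrame({
        "S": agg["sense_n"],
        "A": agg["antisense_n"],
        "replicate_count": sub.groupby("gene_id")["sample_id"].nunique(),
    })
    table["D"] = np.log10(table["S"] / table["A"])
    return table.sort_index()


def change_table(
    dir_t: pd.DataFrame,
    dir_c: pd.DataFrame,
    label_t: str = "treated",
    label_c: str = "control",
) -> pd.DataFrame:
    """Per-gene condition changes computed from two directionality tables.

    log2FC_sense and log2FC_divergent are ratios of the pseudocounted means;
    delta_directionality = (D_t - D_c) * log2(10), which by construction
    equals log2FC_sense - log2FC_divergent.
    """
    common = dir_t.index.intersection(dir_c.index)
    t, c = dir_t.loc[common], dir_c.loc[common]
    out = pd.DataFrame(index=common)
    out["log2FC_sense"] = np.log2(t["S"] / c["S"])
    out["log2FC_divergent"] = np.log2(t["A"] / c["A"])
    out["delta_directionality"] = (t["D"] - c["D"]) * LOG2_10
    out["condition_pair"] = f"{label_t}/{label_c}"
    return out.sort_index()
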