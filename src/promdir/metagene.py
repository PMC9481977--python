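"""TSS-anchored, strand-oriented signal matrices and mean profiles.

Per-base tracks (nucleosome occupancy, factor binding and the like) are
normalized over their total signal, log2-transformed, then sampled into a
genes x offsets matrix centred on the TSS with transcription running left to
right. Missing data (off-chromosome positions) is kept distinct from zero
signal as NaN.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord

logger = logging.getLogger(__name__)


def normalize_track(
    track: Mapping[str, np.ndarray],
    pseudocount: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Divide by the track's total signal across all chromosomes, then log2.

    Output value = log2(value / total + pseudocount). The input must be
    non-negative with a positive total.
    """
    arrays = {c: np.asarray(v, dtype=float) for c, v in track.items()}
    total = float(sum(a.sum() for a in arrays.values()))
    if any((a < 0).any() for a in arrays.values()):
        raise ValueError("track values must be non-negative")
    if total <= 0:
        raise ValueError("track has zero total signal")
    return {c: np.log2(a / total + pseudocount) for c, a in arrays.items()}


def matrix_at_tss(
    genes: Sequence[GeneRecord],
    track: Mapping[str, np.ndarray],
    upstream: int = 500,
    downstream: int = 500,
    skip_zeros: bool = False,
) -> pd.DataFrame:
    """Genes x offsets signal matrix centred on the TSS.

    Column j (offset j - upstream) holds the signal at tss - upstream + j
    for plus-strand genes and tss + upstream - j for minus-strand genes, so
    transcription always runs left to right. Off-chromosome positions are
    NaN. With ``skip_zeros``, rows whose finite values are all zero are
    dropped and their count logged.
    """
    width = upstream + downstream
    offsets = np.arange(-upstream, downstream)
    rows = np.full((len(genes), width), np.nan)
    for i, g in enumerate(genes):
        if g.chrom not in track:
            raise KeyError(f"track lacks chromosome {g.chrom!r}")
        vec = np.asarray(track[g.chrom], dtype=float)
        if g.strand == "+":
            positions = g.tss + offsets
        else:
            positions = g.tss - offsets
        valid = (positions >= 0) & (positions < vec.size)
        rows[i, valid] = vec[positions[valid]]
    matrix = pd.DataFrame(rows, index=[g.gene_id for g in genes],
                          columns=offsets)
    if skip_zeros:
        finite = matrix.notna()
        allzero = ((matrix.fillna(0.0) == 0.0) | ~finite).all(axis=1) \
            & finite.any(axis=1)
        n_drop = int(allzero.sum())
        if n_drop:
            logger.info("matrix_at_tss: dropped %d all-zero rows", n_drop)
        matrix = matrix[~allzero]
    return matrix


def mean_profile(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-offset mean ignoring missing values, plus per-offset n.

    Offsets where every row is missing come back as NaN.
    """
    if len(matrix) == 0:
        raise ValueError("matrix must have at least one row")
    n = matrix.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = matrix.mean(axis=0, skipna=True)
    means[n == 0] = np.nan
    return means, n
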