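"""Lancaster Estimator of Independence (LEI) for marker informativeness.

The statistic scores how strongly the genotype distribution of a biallelic
marker depends on population membership, using allele frequencies alone.
Genotype counts per population are reconstructed under Hardy-Weinberg
equilibrium (HWE) from the reference-allele frequency ``f_j`` and sample
count ``c_j``:

    n1_j = c_j (1 - f_j)^2      (mm)
    n2_j = 2 c_j f_j (1 - f_j)  (mM)
    n3_j = c_j f_j^2            (MM)

The 3-by-k joint distribution ``p_ij = n_ij / n`` (``n = sum c_j``) then
yields the mean-square-contingency-type estimator

    theta^2 = sum_ij p_ij^2 / (p_i+ p_+j) - 1

with 0 <= theta^2 <= min(3, k) - 1: the value is 0 exactly when every
population shares the same frequency, 1 at the two-population maximum
(opposite fixed alleles), and bounded by 2 for k >= 3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import MarkerFrequencyTable, PopulationPanel

__all__ = [
    "GenotypePopulationJoint",
    "LeiScore",
    "hwe_expected_counts",
    "joint_distribution",
    "lei",
    "lei_table",
    "lei_from_frequency_matrix",
    "lei_upper_bound",
]

logger = logging.getLogger(__name__)

_NORMALIZATION_TOL = 1e-12


def lei_upper_bound(k: int) -> float:
    """Theoretical maximum ``min(3, k) - 1`` of the statistic."""
    return float(min(3, k) - 1)


@dataclass(frozen=True)
class GenotypePopulationJoint:
    """Estimated 3-by-k joint distribution of genotype vs population.

    Rows index genotypes (mm, mM, MM); columns index populations.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != 3 or p.shape[1] < 2:
            raise ValueError(f"joint must be 3 x k (k >= 2), got {p.shape}")
        if np.any(p < 0):
            raise ValueError("joint probabilities must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"joint probabilities must sum to 1, got {total}")
        p.setflags(write=False)
        object.__setattr__(self, "p", p)

    @property
    def k(self) -> int:
        return self.p.shape[1]

    @property
    def row_marginals(self) -> np.ndarray:
        """Genotype marginals p_i+ (length 3)."""
        return self.p.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        """Population marginals p_+j = c_j / n (length k)."""
        return self.p.sum(axis=0)


@dataclass(frozen=True)
class LeiScore:
    """LEI value for one marker; ``theta2`` is NaN when frequencies are missing."""

    marker_id: str
    theta2: float
    k: int

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.theta2)


def hwe_expected_counts(f: float, c: float) -> tuple[float, float, float]:
    """Expected genotype counts (mm, mM, MM) under HWE.

    Parameters
    ----------
    f
        Reference-allele frequency, in [0, 1].
    c
        Population sample count, > 0 (any positive real).

    Returns
    -------
    ``(c (1-f)^2, 2 c f (1-f), c f^2)``; the triple sums to ``c``.
    """
    f = float(f)
    c = float(c)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"reference-allele frequency must be in [0, 1], got {f}")
    if not c > 0:
        raise ValueError(f"sample count must be > 0, got {c}")
    return (c * (1.0 - f) ** 2, 2.0 * c * f * (1.0 - f), c * f * f)


def joint_distribution(freqs, panel: PopulationPanel) -> GenotypePopulationJoint:
    """HWE-expected joint distribution of genotype and population for one marker."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (panel.k,):
        raise ValueError(
            f"need one frequency per population ({panel.k}), got shape {freqs.shape}"
        )
    counts = np.empty((3, panel.k))
    for j, (f, c) in enumerate(zip(freqs, panel.counts)):
        try:
            counts[:, j] = hwe_expected_counts(f, c)
        except ValueError as exc:
            raise ValueError(f"population {panel.labels[j]!r}: {exc}") from exc
    return GenotypePopulationJoint(counts / panel.n)


def lei(joint: GenotypePopulationJoint) -> float:
    """LEI statistic ``theta^2`` of a genotype-population joint distribution.

    Terms with a zero genotype marginal contribute 0 (all their cells are
    exactly 0); negative round-off is clamped at 0.
    """
    p = joint.p
    row = joint.row_marginals
    col = joint.col_marginals
    denom = np.outer(row, col)
    ratio = np.zeros_like(p)
    nz = denom > 0
    ratio[nz] = p[nz] ** 2 / denom[nz]
    return max(0.0, float(ratio.sum() - 1.0))


def lei_from_frequency_matrix(freqs: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Vectorised LEI over many markers.

    Parameters
    ----------
    freqs
        ``(m, k)`` reference-allele frequencies; rows with any NaN give NaN.
    counts
        Either a length-``k`` vector of panel counts or an ``(m, k)`` matrix
        of per-marker counts.

    Returns
    -------
    Length-``m`` array of theta^2 values.
    """
    F = np.asarray(freqs, dtype=float)
    if F.ndim != 2:
        raise ValueError("freqs must be 2-D (markers x populations)")
    C = np.asarray(counts, dtype=float)
    if C.ndim == 1:
        C = np.broadcast_to(C, F.shape)
    if C.shape != F.shape:
        raise ValueError("counts must be length k or shaped like freqs")

    valid = np.all(np.isfinite(F), axis=1) & np.all(C > 0, axis=1)
    out = np.full(F.shape[0], np.nan)
    if not valid.any():
        return out
    F = F[valid]
    C = C[valid]
    if np.any((F < 0) | (F > 1)):
        raise ValueError("frequencies must lie in [0, 1]")

    n = C.sum(axis=1, keepdims=True)
    w = C / n  # column marginals p_+j
    # p[i, :, :] stacked over the three genotype rows
    p = np.stack(
        [w * (1.0 - F) ** 2, 2.0 * w * F * (1.0 - F), w * F**2], axis=1
    )  # (m, 3, k)
    row = p.sum(axis=2)  # (m, 3)
    denom = row[:, :, None] * w[:, None, :]
    ratio = np.divide(p**2, denom, out=np.zeros_like(p), where=denom > 0)
    theta2 = np.maximum(0.0, ratio.sum(axis=(1, 2)) - 1.0)
    out[valid] = theta2
    return out


def lei_table(table: MarkerFrequencyTable) -> list[LeiScore]:
    """LEI score per marker of a frequency table, in input order.

    Markers with any missing frequency receive a NaN score and are logged;
    they are never silently imputed. Per-marker sample counts (from genotype
    data) are honoured when the table carries them.
    """
    if table.n_markers == 0:
        raise ValueError("frequency table is empty")
    counts = (
        table.per_marker_counts
        if table.per_marker_counts is not None
        else table.panel.counts
    )
    theta2 = lei_from_frequency_matrix(table.freqs, counts)
    k = table.panel.k
    scores = [
        LeiScore(marker_id=mid, theta2=float(t), k=k)
        for mid, t in zip(table.ids, theta2)
    ]
    n_missing = int(np.isnan(theta2).sum())
    if n_missing:
        missing_ids = [s.marker_id for s in scores if s.is_missing]
        logger.warning(
            "%d of %d markers have missing frequencies and no LEI score "
            "(first few: %s)",
            n_missing,
            table.n_markers,
            ", ".join(missing_ids[:5]),
        )
    if n_missing == table.n_markers:
        logger.warning("all markers have missing frequencies; no scores computed")
    return scores
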