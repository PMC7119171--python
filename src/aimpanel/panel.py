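"""AIM panel construction: score-threshold filtering and physical-distance thinning.

A scored marker table is a :class:`pandas.DataFrame` with columns
``SNPID, Chromosome, [Position,] Ref_Allele, <pop>_Freq..., Score``
(``Method`` optional). Thinning by a minimum physical distance serves as a
cheap proxy for removing linkage-disequilibrium redundancy: within each
chromosome, markers are visited in descending score and kept only if they
lie at least ``spacing_kb`` kilobases from every marker already kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lei import lei_upper_bound

__all__ = ["PanelSpec", "threshold_filter", "spacing_filter", "build_panel", "scored_table"]


@dataclass(frozen=True)
class PanelSpec:
    """Panel construction parameters.

    threshold: minimum score to retain a marker (inclusive).
    spacing_kb: minimum pairwise distance between kept markers on the same
        chromosome, in kilobases; 0 disables thinning.
    top_k: optional cap on final panel size (best scores kept).
    """

    method: str = "LEI"
    threshold: float = 0.0
    spacing_kb: float = 0.0
    top_k: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.spacing_kb < 0:
            raise ValueError("spacing_kb must be >= 0")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def validate_for_k(self, k: int) -> None:
        """Check an LEI threshold against the k-population score range."""
        if self.method.upper() == "LEI":
            hi = lei_upper_bound(k)
            if not 0.0 <= self.threshold <= hi:
                raise ValueError(
                    f"LEI threshold must be in [0, {hi}] for k={k}, "
                    f"got {self.threshold}"
                )


def scored_table(freq_table, scores, method: str = "LEI") -> pd.DataFrame:
    """Join a frequency table with per-marker scores into a scored table."""
    df = freq_table.to_dataframe()
    score_values = np.asarray(
        [s.theta2 if hasattr(s, "theta2") else s for s in scores], dtype=float
    )
    if len(score_values) != len(df):
        raise ValueError("one score required per marker")
    df = df.copy()
    df["Score"] = score_values
    df["Method"] = method
    return df


def threshold_filter(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain markers with score >= threshold, input order preserved.

    Markers with a missing score are dropped.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    keep = table["Score"].to_numpy(dtype=float) >= threshold
    return table.loc[keep].copy()


def spacing_filter(table: pd.DataFrame, spacing_kb: float) -> pd.DataFrame:
    """Greedy per-chromosome thinning at a minimum physical distance.

    Markers are visited in descending score (ties: ascending position, then
    lexicographic id); a marker is kept iff it is >= ``spacing_kb`` kb from
    every already-kept marker on its chromosome. Rows come back in the
    original table order.
    """
    if spacing_kb < 0:
        raise ValueError("spacing_kb must be >= 0")
    if spacing_kb == 0 or len(table) == 0:
        return table.copy()
    if "Position" not in table.columns:
        raise ValueError("spacing filter requires a Position column")
    pos = table["Position"].astype(float).to_numpy()
    if not np.all(np.isfinite(pos)):
        bad = table.loc[~np.isfinite(pos), "SNPID"].tolist()
        raise ValueError(f"markers lack positions, cannot apply spacing: {bad[:10]}")

    min_bp = spacing_kb * 1000.0
    score = table["Score"].to_numpy(dtype=float)
    chrom = table["Chromosome"].astype(str).to_numpy()
    ids = table["SNPID"].astype(str).to_numpy()
    order = sorted(range(len(table)), key=lambda i: (-score[i], pos[i], ids[i]))

    kept_by_chrom: dict[str, list[float]] = {}
    kept_rows: list[int] = []
    for i in order:
        placed = kept_by_chrom.setdefault(chrom[i], [])
        if all(abs(pos[i] - q) >= min_bp for q in placed):
            placed.append(pos[i])
            kept_rows.append(i)
    kept_rows.sort()
    return table.iloc[kept_rows].copy()


def build_panel(table: pd.DataFrame, spec: PanelSpec) -> pd.DataFrame:
    """Threshold-filter, thin by spacing, cap at top_k; sort by descending score.

    Ties in the final sort are broken by ascending position then id, matching
    the spacing filter's visiting order.
    """
    out = threshold_filter(table, spec.threshold)
    out = spacing_filter(out, spec.spacing_kb)
    sort_cols = ["Score"]
    ascending = [False]
    if "Position" in out.columns:
        sort_cols.append("Position")
        ascending.append(True)
    sort_cols.append("SNPID")
    ascending.append(True)
    out = out.sort_values(sort_cols, ascending=ascending, kind="mergesort")
    if spec.top_k is not None:
        out = out.head(spec.top_k)
    return out.reset_index(drop=True)
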