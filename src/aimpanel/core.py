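"""Core data containers: population panels, frequency tables, genotype matrices.

Conventions used throughout the package:

* A marker is biallelic with reference allele ``M`` and alternate allele
  ``m``; ``f_j`` is the reference-allele frequency in population ``j`` and
  genotypes are coded 0/1/2 as counts of the reference allele.
* Missing values are represented as ``NaN`` in floating-point arrays.
* Population sample counts ``c_j`` may be arbitrary positive reals so that
  "equal weighting" (``c_j = 1`` for all populations) is expressible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationPanel",
    "MarkerFrequencyTable",
    "GenotypeMatrix",
]


@dataclass(frozen=True)
class PopulationPanel:
    """Ordered set of ancestral populations with per-population sample counts.

    Parameters
    ----------
    labels
        Distinct population names ``y_1 ... y_k``.
    counts
        Per-population sample sizes ``c_j`` (positive reals). Defaults to
        equal weights ``c_j = 1``.
    """

    labels: tuple[str, ...]
    counts: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if self.k < 2:
            raise ValueError(f"need at least 2 populations, got {self.k}")
        if len(set(labels)) != self.k:
            raise ValueError("population labels must be unique")
        counts = self.counts
        if counts is None:
            counts = np.ones(self.k)
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (self.k,):
            raise ValueError(
                f"counts shape {counts.shape} does not match {self.k} populations"
            )
        if not np.all(counts > 0):
            raise ValueError("all population sample counts must be > 0")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> float:
        """Total sample size ``n = sum(c_j)``."""
        return float(self.counts.sum())

    def with_counts(self, counts) -> "PopulationPanel":
        return PopulationPanel(self.labels, np.asarray(counts, dtype=float))


@dataclass
class MarkerFrequencyTable:
    """Per-marker reference-allele frequencies across a population panel.

    ``freqs`` is an ``(m, k)`` float array; missing frequencies are ``NaN``.
    ``per_marker_counts``, when present, holds the per-marker non-missing
    sample counts used to estimate each frequency (as produced from genotype
    data); otherwise the panel-level counts apply to every marker.
    """

    panel: PopulationPanel
    ids: list[str]
    freqs: np.ndarray
    chromosomes: list[str] = None  # type: ignore[assignment]
    positions: np.ndarray | None = None
    ref_alleles: list[str] = None  # type: ignore[assignment]
    alt_alleles: list[str] = None  # type: ignore[assignment]
    per_marker_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(x) for x in self.ids]
        m = len(self.ids)
        if len(set(self.ids)) != m:
            dupes = sorted({x for x in self.ids if self.ids.count(x) > 1})
            raise ValueError(f"duplicate marker ids: {dupes[:5]}")
        self.freqs = np.asarray(self.freqs, dtype=float).reshape(m, self.panel.k)
        finite = self.freqs[np.isfinite(self.freqs)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            bad = np.argwhere(
                np.isfinite(self.freqs) & ((self.freqs < 0) | (self.freqs > 1))
            )
            i, j = bad[0]
            raise ValueError(
                f"frequency out of [0, 1] for marker {self.ids[i]!r}, "
                f"population {self.panel.labels[j]!r}: {self.freqs[i, j]}"
            )
        if self.chromosomes is None:
            self.chromosomes = ["0"] * m
        else:
            self.chromosomes = [str(x) for x in self.chromosomes]
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
        if self.ref_alleles is None:
            self.ref_alleles = ["A"] * m
        if self.alt_alleles is None:
            self.alt_alleles = ["G"] * m
        if self.per_marker_counts is not None:
            self.per_marker_counts = np.asarray(self.per_marker_counts, dtype=float)
            if self.per_marker_counts.shape != (m, self.panel.k):
                raise ValueError("per_marker_counts shape must be (m, k)")

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with one ``<pop>_Freq`` column per population."""
        data: dict = {
            "SNPID": self.ids,
            "Chromosome": self.chromosomes,
        }
        if self.positions is not None:
            data["Position"] = pd.Series(self.positions).astype("Int64")
        data["Ref_Allele"] = self.ref_alleles
        data["Alt_Allele"] = self.alt_alleles
        for j, pop in enumerate(self.panel.labels):
            data[f"{pop}_Freq"] = self.freqs[:, j]
        return pd.DataFrame(data)

    def subset(self, marker_ids) -> "MarkerFrequencyTable":
        """Restrict to the given markers, in the given order."""
        index = {mid: i for i, mid in enumerate(self.ids)}
        missing = [m for m in marker_ids if m not in index]
        if missing:
            raise KeyError(f"markers absent from table: {missing[:10]}")
        rows = [index[m] for m in marker_ids]
        return MarkerFrequencyTable(
            panel=self.panel,
            ids=[self.ids[i] for i in rows],
            freqs=self.freqs[rows],
            chromosomes=[self.chromosomes[i] for i in rows],
            positions=None if self.positions is None else self.positions[rows],
            ref_alleles=[self.ref_alleles[i] for i in rows],
            alt_alleles=[self.alt_alleles[i] for i in rows],
            per_marker_counts=(
                None
                if self.per_marker_counts is None
                else self.per_marker_counts[rows]
            ),
        )


@dataclass
class GenotypeMatrix:
    """Samples-by-markers reference-allele counts with population labels.

    ``G`` is an ``(n_samples, n_markers)`` float array with entries in
    {0, 1, 2} or ``NaN`` for missing genotypes.
    """

    sample_ids: list[str]
    population_labels: list[str]
    marker_ids: list[str]
    G: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.population_labels = [str(x) for x in self.population_labels]
        self.marker_ids = [str(x) for x in self.marker_ids]
        n, m = len(self.sample_ids), len(self.marker_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(self.population_labels) != n:
            raise ValueError("one population label required per sample")
        self.G = np.asarray(self.G, dtype=float).reshape(n, m)
        observed = self.G[np.isfinite(self.G)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            bad = np.argwhere(
                np.isfinite(self.G) & ~np.isin(self.G, (0.0, 1.0, 2.0))
            )
            i, j = bad[0]
            raise ValueError(
                f"genotype must be 0/1/2 or missing; sample "
                f"{self.sample_ids[i]!r}, marker {self.marker_ids[j]!r} has "
                f"{self.G[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lbl in self.population_labels:
            seen.setdefault(lbl)
        return list(seen)

    def population_indices(self) -> dict[str, np.ndarray]:
        labels = np.asarray(self.population_labels)
        return {pop: np.flatnonzero(labels == pop) for pop in self.populations}

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        index = {mid: i for i, mid in enumerate(self.marker_ids)}
        missing = [m for m in marker_ids if m not in index]
        if missing:
            raise KeyError(f"markers absent from genotype matrix: {missing[:10]}")
        cols = [index[m] for m in marker_ids]
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            population_labels=self.population_labels,
            marker_ids=list(marker_ids),
            G=self.G[:, cols],
        )
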