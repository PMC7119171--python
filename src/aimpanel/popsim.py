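"""Synthetic population-genetic data: ancestral frequencies, HWE cohorts, admixture.

The divergence model is Balding-Nichols: per marker an ancestral frequency
``p`` is drawn from a base law (default Uniform(0.05, 0.95)) and each
population's frequency is Beta(p (1-F)/F, (1-p) (1-F)/F), so E[f] = p and
Var[f] = F p (1-p) with ``F`` playing the role of FST. Genotypes within a
population are Binomial(2, f) per sample and marker (HWE, unlinked markers).
Admixed individuals carry Dirichlet ancestry proportions ``q`` and draw each
genotype as Binomial(2, sum_j q_j f_j) — admixture acts at the frequency
level, which is adequate for unlinked markers; no LD or local-ancestry
blocks are simulated.

All randomness flows from a single seed through named
:class:`numpy.random.SeedSequence` children, so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, MarkerFrequencyTable, PopulationPanel

__all__ = [
    "SimulationConfig",
    "AdmixedCohort",
    "simulate_ancestral_frequencies",
    "simulate_genotypes",
    "simulate_admixed",
]

_STAGE = {"frequencies": 11, "genotypes": 23, "admixed": 37}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE[stage])))


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for the synthetic three-stage pipeline.

    Defaults mirror a diverse continental-scale panel: k=3 ancestral
    populations at FST 0.15, 100 samples per population, 200 admixed samples
    with uniform Dirichlet(1, 1, 1) ancestry proportions.
    """

    k: int = 3
    m: int = 1000
    fst: float = 0.15
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    samples_per_pop: int = 100
    n_admixed: int = 200
    dirichlet_alpha: tuple[float, ...] = None  # type: ignore[assignment]
    seed: int = 1

    def __post_init__(self) -> None:
        if self.k < 2 or self.m < 1 or self.samples_per_pop < 1 or self.n_admixed < 1:
            raise ValueError("all sizes must be >= 1 (k >= 2)")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        lo, hi = self.base_freq_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("base_freq_range must be an interval within [0, 1]")
        alpha = self.dirichlet_alpha
        if alpha is None:
            alpha = (1.0,) * self.k
        alpha = tuple(float(a) for a in alpha)
        if len(alpha) != self.k or any(a <= 0 for a in alpha):
            raise ValueError("dirichlet_alpha must be k positive concentrations")
        object.__setattr__(self, "dirichlet_alpha", alpha)

    @property
    def population_labels(self) -> tuple[str, ...]:
        return tuple(f"Pop{j + 1}" for j in range(self.k))


@dataclass
class AdmixedCohort:
    """Admixed genotypes together with the true ancestry proportions."""

    genotypes: GenotypeMatrix
    Q_true: np.ndarray

    def __post_init__(self) -> None:
        self.Q_true = np.asarray(self.Q_true, dtype=float)
        if self.Q_true.shape[0] != self.genotypes.n_samples:
            raise ValueError("one ancestry row required per sample")
        if np.any(self.Q_true < 0) or np.any(
            np.abs(self.Q_true.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("ancestry proportions must lie on the simplex")


def simulate_ancestral_frequencies(cfg: SimulationConfig) -> MarkerFrequencyTable:
    """Balding-Nichols frequency table for ``cfg.m`` markers, ``cfg.k`` populations.

    Markers are placed on a single synthetic chromosome at 10 kb intervals so
    spacing-based thinning is exercised without a genome map.
    """
    rng = _stage_rng(cfg.seed, "frequencies")
    lo, hi = cfg.base_freq_range
    p = rng.uniform(lo, hi, size=cfg.m)
    F = cfg.fst
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    freqs = rng.beta(a[:, None], b[:, None], size=(cfg.m, cfg.k))
    panel = PopulationPanel(
        cfg.population_labels, np.full(cfg.k, float(cfg.samples_per_pop))
    )
    return MarkerFrequencyTable(
        panel=panel,
        ids=[f"snp{i + 1}" for i in range(cfg.m)],
        freqs=freqs,
        chromosomes=["1"] * cfg.m,
        positions=np.arange(1, cfg.m + 1, dtype=float) * 10_000.0,
        ref_alleles=["A"] * cfg.m,
        alt_alleles=["G"] * cfg.m,
    )


def simulate_genotypes(
    table: MarkerFrequencyTable, samples_per_pop: int, seed: int
) -> GenotypeMatrix:
    """HWE genotype cohort: Binomial(2, f_j) per sample and marker."""
    if np.any(~np.isfinite(table.freqs)):
        raise ValueError("frequency table contains missing frequencies")
    rng = _stage_rng(seed, "genotypes")
    k = table.panel.k
    blocks, sample_ids, labels = [], [], []
    for j, pop in enumerate(table.panel.labels):
        blocks.append(
            rng.binomial(2, table.freqs[:, j], size=(samples_per_pop, table.n_markers))
        )
        sample_ids.extend(f"{pop}_s{i + 1}" for i in range(samples_per_pop))
        labels.extend([pop] * samples_per_pop)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        population_labels=labels,
        marker_ids=list(table.ids),
        G=np.vstack(blocks).astype(float),
    )


def simulate_admixed(
    table: MarkerFrequencyTable,
    n_admixed: int,
    dirichlet_alpha,
    seed: int,
) -> AdmixedCohort:
    """Admixed cohort under the frequency-mixture model.

    Each sample draws ``q ~ Dirichlet(alpha)``; each genotype is
    Binomial(2, sum_j q_j f_j). Returns genotypes plus the true Q matrix.
    """
    if np.any(~np.isfinite(table.freqs)):
        raise ValueError("frequency table contains missing frequencies")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (table.panel.k,) or np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be k positive concentrations")
    rng = _stage_rng(seed, "admixed")
    Q = rng.dirichlet(alpha, size=n_admixed)  # (n, k)
    mix = Q @ table.freqs.T  # (n, m) per-sample marker frequencies
    G = rng.binomial(2, mix).astype(float)
    genotypes = GenotypeMatrix(
        sample_ids=[f"adm_s{i + 1}" for i in range(n_admixed)],
        population_labels=["ADMIXED"] * n_admixed,
        marker_ids=list(table.ids),
        G=G,
    )
    return AdmixedCohort(genotypes=genotypes, Q_true=Q)
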