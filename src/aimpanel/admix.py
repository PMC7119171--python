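"""Panel validation: supervised ancestry-proportion estimation and PCA separation.

The ancestry-proportion estimator is a supervised maximum-likelihood fit on
the k-simplex. Given parental reference-allele frequencies ``f_mj`` for the
panel markers and an individual's genotypes ``g_m`` (counts of the reference
allele), the model treats each of the two allele copies as drawn from
ancestry ``j`` with probability ``q_j`` and then reference with probability
``f_mj``, so ``g_m ~ Binomial(2, pi_m)`` with ``pi_m = sum_j q_j f_mj``.
The EM update from the uniform start,

    q_j <- q_j * [ sum_m ( g_m f_mj / pi_m + (2 - g_m)(1 - f_mj)/(1 - pi_m) ) ] / (2 M),

is multiplicative, stays on the simplex, and increases the log-likelihood;
iteration stops when max |dq| < 1e-6 or after 500 rounds. Frequencies are
clipped to [1e-6, 1 - 1e-6] to keep the likelihood finite at fixed alleles.

Panel quality is summarised two ways, mirroring common practice: the
entries-wise RMSE between true and estimated ancestry-proportion matrices
(a good panel achieves RMSE < 0.05), and the separation of known population
labels in top-2 principal-component space (explained-variance ratios plus
mean silhouette).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, MarkerFrequencyTable

__all__ = [
    "AncestryProportions",
    "SeparationReport",
    "estimate_ancestry_proportions",
    "rmse_proportions",
    "pca_separation",
]

_FREQ_EPS = 1e-6
_EM_TOL = 1e-6
_EM_MAX_ITER = 500


@dataclass(frozen=True)
class AncestryProportions:
    """Estimated per-sample ancestry proportions on the k-simplex."""

    sample_ids: tuple[str, ...]
    population_labels: tuple[str, ...]
    Q: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (len(self.sample_ids), len(self.population_labels)):
            raise ValueError("Q must be (n_samples, k)")
        if np.any(Q < -1e-12) or np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("rows of Q must lie on the simplex")
        Q.setflags(write=False)
        object.__setattr__(self, "Q", Q)


@dataclass(frozen=True)
class SeparationReport:
    """PCA summary of how well known population labels separate."""

    explained_variance_ratios: tuple[float, float]
    silhouette: float

    def __post_init__(self) -> None:
        r = self.explained_variance_ratios
        if not (0.0 <= r[1] <= r[0] <= 1.0):
            raise ValueError("explained-variance ratios must be non-increasing in [0, 1]")
        if not -1.0 <= self.silhouette <= 1.0:
            raise ValueError("silhouette must be in [-1, 1]")


def estimate_ancestry_proportions(
    G: GenotypeMatrix, parental: MarkerFrequencyTable
) -> AncestryProportions:
    """Supervised binomial-likelihood EM estimate of ancestry proportions.

    ``G`` holds the admixed samples restricted to the panel markers;
    ``parental`` supplies the per-population reference-allele frequencies for
    those markers. Deterministic: uniform start, multiplicative updates.
    """
    missing = [m for m in G.marker_ids if m not in set(parental.ids)]
    if missing:
        raise KeyError(
            f"{len(missing)} panel markers absent from parental table "
            f"(first few: {missing[:10]})"
        )
    if np.any(~np.isfinite(parental.freqs)):
        raise ValueError("parental frequencies must be non-missing for the panel")
    parental = parental.subset(G.marker_ids)
    F = np.clip(parental.freqs, _FREQ_EPS, 1.0 - _FREQ_EPS)  # (M, k)
    k = parental.panel.k
    n, M = G.n_samples, G.n_markers

    X = G.G
    obs = np.isfinite(X)
    Gm = np.where(obs, X, 0.0)  # reference-allele counts, 0 where missing
    Hm = np.where(obs, 2.0 - X, 0.0)  # alternate-allele counts
    copies = 2.0 * obs.sum(axis=1)  # observed allele copies per sample
    if np.any(copies == 0):
        raise ValueError("every sample needs at least one observed genotype")

    Q = np.full((n, k), 1.0 / k)
    for _ in range(_EM_MAX_ITER):
        P = Q @ F.T  # (n, M) mixture reference-allele probability
        w = (Gm / P) @ F + (Hm / (1.0 - P)) @ (1.0 - F)  # (n, k)
        Q_new = Q * w / copies[:, None]
        Q_new /= Q_new.sum(axis=1, keepdims=True)  # guard round-off drift
        if np.max(np.abs(Q_new - Q)) < _EM_TOL:
            Q = Q_new
            break
        Q = Q_new
    return AncestryProportions(
        sample_ids=tuple(G.sample_ids),
        population_labels=tuple(parental.panel.labels),
        Q=Q,
    )


def rmse_proportions(Q_true, Q_est) -> float:
    """Entries-wise root-mean-square error between two n-by-k proportion matrices."""
    A = np.asarray(Q_true, dtype=float)
    B = Q_est.Q if isinstance(Q_est, AncestryProportions) else np.asarray(Q_est, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean((A - B) ** 2)))


def pca_separation(G: GenotypeMatrix, plot_path: str | None = None) -> SeparationReport:
    """Top-2 PCA of standardised panel genotypes with a label-silhouette summary.

    Optionally writes a PC1-vs-PC2 scatter coloured by population to
    ``plot_path``.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    from .ranking import _standardize

    if len(G.populations) < 2:
        raise ValueError("separation needs at least 2 populations")
    if G.n_samples < 3:
        raise ValueError("separation needs at least 3 samples")
    X, informative = _standardize(G)
    if not informative.any():
        raise ValueError("panel is degenerate: every marker is constant")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    sil = float(silhouette_score(coords, np.asarray(G.population_labels)))
    report = SeparationReport(
        explained_variance_ratios=tuple(float(r) for r in pca.explained_variance_ratio_),
        silhouette=sil,
    )
    if plot_path is not None:
        _plot_pcs(coords, G.population_labels, pca.explained_variance_ratio_, plot_path)
    return report


def _plot_pcs(coords, labels, evr, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(labels)
    for pop in dict.fromkeys(labels):
        sel = labels == pop
        ax.scatter(coords[sel, 0], coords[sel, 1], s=12, label=pop, alpha=0.7)
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
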