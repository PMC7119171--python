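"""Marker informativeness scores from individual-level genotype data.

Four rankings are offered. LEI goes through per-population allele-frequency
estimates and is identical to the frequency-only path on fully observed
data. The PCA, SVM and RF scores are standard embedded feature-selection
measures on the samples-by-markers genotype matrix:

* PCA — explained-variance-weighted sum of squared component loadings of the
  column-standardised matrix;
* SVM — maximum absolute coefficient across per-population linear
  one-vs-rest support-vector classifiers on standardised genotypes;
* RF — mean impurity-decrease importance of a random-forest classifier
  predicting population membership.

Missing genotypes are excluded from allele counts on the LEI path and
mean-imputed per marker for PCA/SVM/RF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, MarkerFrequencyTable, PopulationPanel
from .lei import lei_table

__all__ = [
    "RankingResult",
    "estimate_frequencies",
    "lei_from_genotypes",
    "pca_marker_scores",
    "svm_marker_scores",
    "rf_marker_scores",
    "rank_markers",
]

logger = logging.getLogger(__name__)

METHODS = ("LEI", "PCA", "SVM", "RF")


@dataclass(frozen=True)
class RankingResult:
    """Per-marker scores for one method plus the descending-score ordering."""

    method: str
    marker_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.marker_ids),):
            raise ValueError("one score required per marker")
        finite = scores[np.isfinite(scores)]
        if finite.size and finite.min() < 0:
            raise ValueError("scores must be non-negative")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))

    @property
    def ordering(self) -> list[str]:
        """Scored marker ids sorted by descending score (ties: input order).

        Markers without a score (missing frequencies) are excluded.
        """
        scored = [i for i, s in enumerate(self.scores) if np.isfinite(s)]
        scored.sort(key=lambda i: (-self.scores[i], i))
        return [self.marker_ids[i] for i in scored]

    def top(self, n: int) -> list[str]:
        return self.ordering[:n]


def estimate_frequencies(G: GenotypeMatrix) -> MarkerFrequencyTable:
    """Per-population reference-allele frequencies from genotype codes.

    For marker ``j`` and population ``p`` the estimate is the allele count
    over non-missing samples divided by twice their number. The returned
    table carries per-marker non-missing counts; the attached panel reports
    the per-population maximum.
    """
    pops = G.populations
    if len(pops) < 2:
        raise ValueError("genotype matrix must contain at least 2 populations")
    idx = G.population_indices()
    m = G.n_markers
    freqs = np.full((m, len(pops)), np.nan)
    counts = np.zeros((m, len(pops)))
    for j, pop in enumerate(pops):
        block = G.G[idx[pop]]
        obs = np.isfinite(block)
        n_obs = obs.sum(axis=0)
        allele_sum = np.nansum(block, axis=0)
        with np.errstate(invalid="ignore"):
            freqs[:, j] = np.where(n_obs > 0, allele_sum / (2.0 * n_obs), np.nan)
        counts[:, j] = n_obs
        n_empty = int((n_obs == 0).sum())
        if n_empty:
            logger.warning(
                "population %r has no observed genotypes at %d marker(s); "
                "frequency set to missing",
                pop,
                n_empty,
            )
    panel = PopulationPanel(tuple(pops), np.maximum(counts.max(axis=0), 1.0))
    return MarkerFrequencyTable(
        panel=panel,
        ids=list(G.marker_ids),
        freqs=freqs,
        per_marker_counts=counts,
    )


def lei_from_genotypes(G: GenotypeMatrix) -> RankingResult:
    """LEI ranking via estimated frequencies (two-step path, composed)."""
    table = estimate_frequencies(G)
    scores = np.array([s.theta2 for s in lei_table(table)])
    return RankingResult("LEI", tuple(G.marker_ids), scores)


def _standardize(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing entries, centre and scale columns.

    Returns the standardised matrix and a boolean mask of non-constant
    markers; constant (zero-variance) columns are zeroed and flagged.
    """
    X = np.array(G.G, dtype=float)
    col_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_rows, nan_cols = np.nonzero(~np.isfinite(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    informative = std > 0
    X -= mean
    X[:, informative] /= std[informative]
    X[:, ~informative] = 0.0
    return X, informative


def pca_marker_scores(G: GenotypeMatrix, n_components: int = 2) -> RankingResult:
    """Loading-based marker scores from PCA of standardised genotypes.

    The score of marker ``j`` is ``sum_c evr_c * loading_{cj}^2`` over the
    top ``n_components`` components (explained-variance ratio ``evr``);
    squaring makes it sign-invariant. Constant markers score 0.
    """
    from sklearn.decomposition import PCA

    if G.n_samples < 2:
        raise ValueError("PCA scoring needs at least 2 samples")
    max_comp = min(G.n_samples, G.n_markers)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    X, _ = _standardize(G)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    loadings2 = pca.components_**2  # (n_components, m)
    scores = pca.explained_variance_ratio_ @ loadings2
    return RankingResult("PCA", tuple(G.marker_ids), np.maximum(scores, 0.0))


def svm_marker_scores(G: GenotypeMatrix, C: float = 1.0, seed: int = 1) -> RankingResult:
    """Coefficient-based marker scores from linear one-vs-rest SVMs.

    Score of a marker = maximum absolute coefficient across the per-population
    classifiers fit on standardised genotypes. ``C`` is the usual
    regularisation strength of the hinge-loss classifier.
    """
    from sklearn.svm import LinearSVC

    pops = G.populations
    if len(pops) < 2:
        raise ValueError("SVM scoring needs at least 2 populations")
    sizes = [len(v) for v in G.population_indices().values()]
    if min(sizes) < 2:
        raise ValueError("SVM scoring needs at least 2 samples per population")
    X, informative = _standardize(G)
    y = np.asarray(G.population_labels)
    clf = LinearSVC(C=C, multi_class="ovr", dual=True, random_state=seed, max_iter=20000)
    clf.fit(X, y)
    coef = np.atleast_2d(clf.coef_)
    scores = np.abs(coef).max(axis=0)
    scores[~informative] = 0.0
    return RankingResult("SVM", tuple(G.marker_ids), scores)


def rf_marker_scores(
    G: GenotypeMatrix, n_trees: int = 500, seed: int = 1
) -> RankingResult:
    """Impurity-decrease importances from a random-forest population classifier."""
    from sklearn.ensemble import RandomForestClassifier

    if len(G.populations) < 2:
        raise ValueError("RF scoring needs at least 2 populations")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, _ = _standardize(G)
    y = np.asarray(G.population_labels)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X, y)
    return RankingResult("RF", tuple(G.marker_ids), clf.feature_importances_)


def rank_markers(G: GenotypeMatrix, method: str = "LEI", **kwargs) -> RankingResult:
    """Dispatch to one of the four ranking methods by name."""
    method = method.upper()
    if method == "LEI":
        return lei_from_genotypes(G)
    if method == "PCA":
        return pca_marker_scores(G, **kwargs)
    if method == "SVM":
        return svm_marker_scores(G, **kwargs)
    if method == "RF":
        return rf_marker_scores(G, **kwargs)
    raise ValueError(f"unknown ranking method {method!r}; choose from {METHODS}")
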