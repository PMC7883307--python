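"""PAIRS: projection angle index of response similarity.

Each neuron's 246-sample response vector is projected onto a common PCA basis
(8 components by default, chosen to capture >90% of population variance) and
unit-normalised, so the dot product of two feature vectors is the cosine of
the angle between them.  For each neuron the mean angle to its k nearest
neighbours is computed; the PAIRS statistic is the median of these means.
Clustering of response profiles makes the statistic small; significance is
assessed against surrogate populations in which each feature coordinate is
drawn independently from its empirical marginal, which preserves per-component
structure while destroying between-component dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .config import AnalysisConfig
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class PcaBasis:
    mean: np.ndarray  # (d,)
    components: np.ndarray  # (n_components, d), orthonormal rows
    variance_captured: float  # cumulative fraction


@dataclass
class PairsResult:
    observed: float  # median theta_z^(k), degrees
    per_neuron: np.ndarray  # theta_z^(k) per neuron, degrees
    k: int
    surrogate_values: np.ndarray  # surrogate PAIRS statistics, degrees
    p_value: float
    n_surrogates: int
    n_neurons: int
    variance_captured: Optional[float] = None
    label: Optional[str] = None


def fit_pca_basis(vectors: np.ndarray, n_components: int = 8) -> PcaBasis:
    """Fit the common PCA basis on pooled response vectors (mean-centred)."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValidationError("vectors must be 2-D (neurons x samples)")
    n = vectors.shape[0]
    if n < n_components + 1:
        raise ValidationError(
            f"need at least {n_components + 1} neurons to fit {n_components} components, got {n}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(vectors)
    captured = float(pca.explained_variance_ratio_.sum())
    if captured < 0.90:
        log.warning("PCA basis captures only %.1f%% of variance", 100 * captured)
    return PcaBasis(mean=pca.mean_, components=pca.components_, variance_captured=captured)


def project_features(vectors: np.ndarray, basis: PcaBasis) -> tuple[np.ndarray, np.ndarray]:
    """Centred projections onto the basis, unit-normalised per neuron.

    Returns ``(features, kept_index)``; neurons whose projection has zero norm
    are excluded (with a log entry) rather than failing.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    proj = (vectors - basis.mean) @ basis.components.T
    norms = np.linalg.norm(proj, axis=1)
    kept = np.flatnonzero(norms > 0)
    if kept.size < proj.shape[0]:
        log.info("excluding %d zero-norm projections", proj.shape[0] - kept.size)
    return proj[kept] / norms[kept, None], kept


def _knn_angles_batch(features: np.ndarray, k: int) -> np.ndarray:
    """theta_z^(k) in degrees for a batch of populations.

    ``features``: (..., n, d) unit vectors.  For each neuron, angles to all
    others are computed from clamped dot products; the mean over the k smallest
    is returned.  Neighbour ties at the k-th position are broken by neuron
    index, which leaves the mean unchanged (tied values are equal), so a
    partial sort is used.
    """
    n = features.shape[-2]
    if k >= n:
        raise ValidationError(f"k ({k}) must be smaller than the number of neurons ({n})")
    cos = np.clip(features @ np.swapaxes(features, -1, -2), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    idx = np.arange(n)
    theta[..., idx, idx] = np.inf  # exclude self
    theta = np.partition(theta, k - 1, axis=-1)[..., :k]
    return theta.mean(axis=-1)


def knn_mean_angles(features: np.ndarray, k: int = 3) -> np.ndarray:
    """Per-neuron mean angle (degrees) to the k nearest neighbours."""
    features = np.asarray(features, dtype=float)
    return _knn_angles_batch(features, k)


def pairs_statistic(features: np.ndarray, k: int = 3) -> float:
    """Median over neurons of the k-nearest-neighbour mean angle, in degrees."""
    return float(np.median(knn_mean_angles(features, k)))


def _surrogate_features(
    features: np.ndarray,
    n_surrogates: int,
    rng: np.random.Generator,
    mode: str,
    normalise: bool = True,
) -> np.ndarray:
    """(n_surrogates, n, d) surrogate populations with coordinate-wise marginals
    preserved; rows re-unit-normalised unless ``normalise`` is False."""
    n, d = features.shape
    if mode == "resample":
        idx = rng.integers(0, n, size=(n_surrogates, n, d))
    else:  # "permute": each coordinate is a permutation of the empirical values
        idx = np.argsort(rng.random((n_surrogates, n, d)), axis=1)
    surr = np.take_along_axis(features[None, :, :], idx, axis=1)
    if not normalise:
        return surr
    norms = np.linalg.norm(surr, axis=-1, keepdims=True)
    norms[norms == 0] = 1.0
    return surr / norms


def pairs_surrogate_test(
    features: np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator,
    variance_captured: Optional[float] = None,
    label: Optional[str] = None,
) -> PairsResult:
    """One-sided PAIRS test against marginal-resampling surrogates.

    Small angles mean clustering; the p-value is the add-one estimator
    ``p = (1 + #{surrogate PAIRS <= observed}) / (1 + n_surrogates)``, so an
    observed value below all 10,000 surrogates reports p = 1/10001 < 1e-4.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 10:
        raise ValidationError(f"need at least 10 neurons for the PAIRS test, got {n}")
    if config.pairs_surrogates < 100:
        log.warning(
            "only %d surrogates: p-value resolution is %.3f",
            config.pairs_surrogates, 1 / (config.pairs_surrogates + 1),
        )
    k = config.pairs_k
    per_neuron = knn_mean_angles(features, k)
    observed = float(np.median(per_neuron))

    n_surr = config.pairs_surrogates
    surrogate_values = np.empty(n_surr)
    chunk = max(1, int(2e7 // max(1, n * n)))  # bound memory of the angle matrices
    done = 0
    while done < n_surr:
        b = min(chunk, n_surr - done)
        surr = _surrogate_features(features, b, rng, config.pairs_surrogate_mode)
        surrogate_values[done : done + b] = np.median(
            _knn_angles_batch(surr, k), axis=-1
        )
        done += b

    p = (1 + int(np.sum(surrogate_values <= observed))) / (1 + n_surr)
    return PairsResult(
        observed=observed,
        per_neuron=per_neuron,
        k=k,
        surrogate_values=surrogate_values,
        p_value=float(p),
        n_surrogates=n_surr,
        n_neurons=n,
        variance_captured=variance_captured,
        label=label,
    )


MIN_SESSION_NEURONS = 25  # sessions must have strictly more neurons than this


def per_session_pairs(
    vectors_by_session: dict[str, np.ndarray],
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> dict[str, PairsResult]:
    """PAIRS per session within one category (naive or well-trained).

    A common PCA basis is fitted on the pooled vectors of the category; each
    session is then tested separately with surrogates built from its own
    feature marginals.  Sessions with <= 25 neurons are skipped.
    """
    eligible = {
        key: v for key, v in vectors_by_session.items() if v.shape[0] > MIN_SESSION_NEURONS
    }
    for key in vectors_by_session:
        if key not in eligible:
            log.info(
                "skipping session %s: %d neurons (need > %d)",
                key, vectors_by_session[key].shape[0], MIN_SESSION_NEURONS,
            )
    if not eligible:
        return {}
    pooled = np.vstack(list(eligible.values()))
    basis = fit_pca_basis(pooled, config.pca_components)
    results = {}
    for key, vectors in eligible.items():
        feats, _ = project_features(vectors, basis)
        results[key] = pairs_surrogate_test(
            feats, config, rng, variance_captured=basis.variance_captured, label=key
        )
    return results
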