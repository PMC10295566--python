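"""Gender-stratified PCA feature models and Hotelling T2 scoring.

A cohort of feature vectors (age, mass, height, four joint flexions,
striding speed) is z-scored — the features mix years, kilograms, metres,
degrees and hertz, so unstandardised PCA would be dominated by the
degree-valued flexions — and reduced to the principal components that
together explain at least the configured variance fraction (90 % by
default).  A new subject is scored with the Hotelling T2 statistic

    T2 = sum_i t_i^2 / lambda_i,   t = loadings @ z(x),

the squared Mahalanobis-type distance of the subject from the cohort in
the retained PC subspace; larger scores mean a more atypical gait.
Leave-one-out scoring rebuilds the model without the scored subject, so
small cohorts are used fully without information leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .gait_params import FEATURE_ORDER, FEATURE_ORDER_VERSION, GaitFeatureVector

_FORMAT_VERSION = 1


@dataclass
class FeatureModel:
    """Standardisation parameters plus retained principal components.

    ``loadings`` has one orthonormal row per retained PC (d2 x d1);
    ``eigenvalues`` are the PC variances of the standardised data
    (sample covariance, n-1 denominator); ``explained_variance`` their
    fractions of total variance.
    """

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    n_samples: int
    stratum: str
    feature_order: tuple[str, ...] = FEATURE_ORDER

    @property
    def d1(self) -> int:
        return len(self.mean)

    @property
    def d2(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "feature_order_version": FEATURE_ORDER_VERSION,
            "feature_order": list(self.feature_order),
            "stratum": self.stratum,
            "n_samples": self.n_samples,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported feature-model format version")
        return cls(
            mean=np.array(payload["mean"], dtype=float),
            scale=np.array(payload["scale"], dtype=float),
            loadings=np.array(payload["loadings"], dtype=float),
            eigenvalues=np.array(payload["eigenvalues"], dtype=float),
            explained_variance=np.array(payload["explained_variance"], dtype=float),
            n_samples=int(payload["n_samples"]),
            stratum=payload["stratum"],
            feature_order=tuple(payload["feature_order"]),
        )


def _cohort_matrix(cohort: Sequence[GaitFeatureVector]) -> tuple[np.ndarray, str]:
    if len(cohort) < 3:
        raise ValueError(f"need at least 3 cohort samples, got {len(cohort)}")
    strata = {fv.gender for fv in cohort}
    if len(strata) != 1:
        raise ValueError(f"cohort mixes strata {sorted(strata)}")
    X = np.vstack([fv.as_array() for fv in cohort])
    return X, strata.pop()


def build_feature_model(
    cohort: Sequence[GaitFeatureVector], variance_threshold: float = 0.90
) -> FeatureModel:
    """Fit a PCA feature model on a single-stratum cohort.

    Features are z-scored with the cohort mean and sample standard
    deviation (n-1); PCs are retained in decreasing eigenvalue order
    until their cumulative explained variance reaches the threshold
    (at least one PC, and never a numerically null component).
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    X, stratum = _cohort_matrix(cohort)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale <= 1e-10 * np.maximum(np.abs(mean), 1.0))
    if zero.size:
        names = [FEATURE_ORDER[i] for i in zero]
        raise ValueError(f"zero-variance feature(s): {names}")
    Z = (X - mean) / scale

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(Z)
    eigenvalues = pca.explained_variance_
    ratios = pca.explained_variance_ratio_
    # discard numerically null directions (rank-deficient cohorts)
    rank = int(np.sum(eigenvalues > max(eigenvalues[0], 1.0) * 1e-10))
    rank = max(rank, 1)
    cum = np.cumsum(ratios[:rank])
    d2 = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    d2 = min(d2, rank)
    return FeatureModel(
        mean=mean,
        scale=scale,
        loadings=pca.components_[:d2].copy(),
        eigenvalues=eigenvalues[:d2].copy(),
        explained_variance=ratios[:d2].copy(),
        n_samples=X.shape[0],
        stratum=stratum,
    )


def t2_score(
    model: FeatureModel, x: GaitFeatureVector, normalisation: str = "none"
) -> float:
    """Hotelling T2 score of a subject against a feature model.

    The subject is standardised with the model's mean and scale,
    projected onto the retained loadings, and each squared score is
    weighted by the inverse eigenvalue.  ``normalisation="per_pc"``
    divides the sum by the number of retained components.
    """
    if normalisation not in ("none", "per_pc"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    v = x.as_array()
    if not np.all(np.isfinite(v)):
        raise ValueError("feature vector contains non-finite values")
    z = (v - model.mean) / model.scale
    t = model.loadings @ z
    score = float(np.sum(t**2 / model.eigenvalues))
    if normalisation == "per_pc":
        score /= model.d2
    return score


def loo_t2(
    cohort: Sequence[GaitFeatureVector],
    variance_threshold: float = 0.90,
    normalisation: str = "none",
) -> list[float]:
    """Leave-one-out T2 scores over a cohort.

    Each subject is scored against a model fitted on the remaining
    subjects, mirroring how a patient would be scored against a normal
    cohort they do not belong to.
    """
    if len(cohort) < 4:
        raise ValueError("leave-one-out needs at least 4 samples")
    scores = []
    for i, fv in enumerate(cohort):
        rest = [c for j, c in enumerate(cohort) if j != i]
        model = build_feature_model(rest, variance_threshold)
        scores.append(t2_score(model, fv, normalisation))
    return scores


def pc_cosine_similarity(a: FeatureModel, b: FeatureModel, k: int) -> np.ndarray:
    """|cosine| between the first k pairs of loading vectors of two models.

    The absolute value absorbs the sign ambiguity of principal
    components.  Values lie in [0, 1]; 1 means identical directions.
    """
    if a.feature_order != b.feature_order:
        raise ValueError("feature orders differ between models")
    if k > min(a.d2, b.d2):
        raise ValueError(f"k={k} exceeds retained components ({a.d2}, {b.d2})")
    sims = np.empty(k)
    for i in range(k):
        u, v = a.loadings[i], b.loadings[i]
        sims[i] = abs(float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return sims
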