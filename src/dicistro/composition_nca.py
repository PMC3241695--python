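"""Nucleotide composition analysis (NCA) and host prediction.

Host-origin inference for an unclassified viral sequence rests on the
observation that viruses broadly mirror the dinucleotide biases of their
hosts: mammalian and plant viruses suppress CpG (and UpA), while many insect
and fish viruses do not.  The analysis here is:

1. For each sequence compute the 4 mononucleotide frequencies, the 16
   dinucleotide frequencies over overlapping adjacent pairs, and the 16
   observed/expected ratios rho(xy) = p(xy) / (p(x) p(y)).
2. Stack either the raw frequencies (4 + 16 = 20 features) or the
   mononucleotides plus O/E ratios into feature vectors.
3. Fit a canonical (Fisher) discriminant analysis over host classes:
   canonical factors are generalized eigenvectors of the between-class
   scatter B against the (ridge-regularized) pooled within-class scatter W,
   ordered by decreasing eigenvalue; there are at most #classes - 1 of them.
4. Classify a query to the nearest class centroid in canonical space
   (Mahalanobis distance in feature space), with equal class priors by
   default.

Frequency features are linearly dependent (each block sums to 1), and small
classes make W singular, so W is regularized as W + eps*I with
eps = ridge * trace(W) / p before the eigensolve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy.stats import chi2

from .errors import (
    DataError,
    DimensionError,
    InsufficientSequenceError,
    LabelError,
    UndefinedRatioError,
)
from .seqio import GenomeRecord

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

HOST_LABELS = ("mammal", "insect", "plant", "fish")


@dataclass(frozen=True)
class CompositionProfile:
    """Mono/dinucleotide frequencies and observed/expected ratios.

    ``mono[i]`` follows the order A,C,G,T; ``dinuc`` and ``oe`` are 4x4 with
    ``[x, y]`` meaning the pair x followed by y.  Positions containing N are
    excluded from the mononucleotide count and any adjacent pair containing N
    is excluded from the dinucleotide count (windows are linear, not
    circular).  ``oe_defined[x, y]`` is False where the expected frequency
    p(x)p(y) is zero and the ratio is undefined.
    """

    mono: np.ndarray  # (4,)
    dinuc: np.ndarray  # (4, 4)
    oe: np.ndarray  # (4, 4), NaN where undefined
    oe_defined: np.ndarray  # (4, 4) bool
    n_mono: int
    n_dinuc: int


def composition_profile(record: GenomeRecord | str) -> CompositionProfile:
    """Count composition of one sequence (see class docstring for rules)."""
    seq = record.sequence if isinstance(record, GenomeRecord) else record
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    # map A,C,G,T -> 0..3; anything else (N) -> 4
    lut = np.full(256, 4, dtype=np.int8)
    for ch, i in _INDEX.items():
        lut[ord(ch)] = i
    x = lut[codes]
    valid = x < 4
    n_mono = int(valid.sum())
    if n_mono < 2:
        raise InsufficientSequenceError(
            "need at least 2 non-N bases for composition analysis"
        )
    mono_counts = np.bincount(x[valid], minlength=4).astype(float)
    mono = mono_counts / n_mono

    left, right = x[:-1], x[1:]
    pair_ok = (left < 4) & (right < 4)
    n_dinuc = int(pair_ok.sum())
    if n_dinuc < 1:
        raise InsufficientSequenceError("no adjacent non-N pair in sequence")
    dinuc = np.zeros((4, 4))
    np.add.at(dinuc, (left[pair_ok], right[pair_ok]), 1.0)
    dinuc /= n_dinuc

    expected = np.outer(mono, mono)
    defined = expected > 0
    oe = np.full((4, 4), np.nan)
    oe[defined] = dinuc[defined] / expected[defined]
    return CompositionProfile(mono, dinuc, oe, defined, n_mono, n_dinuc)


def gc_content(profile: CompositionProfile) -> float:
    """G+C as a percentage (reported to 1 decimal)."""
    return round(100.0 * (profile.mono[1] + profile.mono[2]), 1)


def au_content(profile: CompositionProfile) -> float:
    """A+U (A+T on the DNA alphabet) as a percentage."""
    return round(100.0 * (profile.mono[0] + profile.mono[3]), 1)


def build_features(profile: CompositionProfile, mode: str = "frequencies") -> np.ndarray:
    """20-feature vector: 4 mononucleotide frequencies then the 16 pairs.

    ``mode="frequencies"`` appends dinucleotide frequencies (the vector then
    sums to 2); ``mode="oe"`` appends observed/expected ratios and raises if
    any ratio is undefined.  Pair order is AA, AC, ..., TT.
    """
    if mode == "frequencies":
        return np.concatenate([profile.mono, profile.dinuc.ravel()])
    if mode == "oe":
        if not profile.oe_defined.all():
            bad = [
                DINUCLEOTIDES[4 * i + j]
                for i in range(4)
                for j in range(4)
                if not profile.oe_defined[i, j]
            ]
            raise UndefinedRatioError(bad)
        return np.concatenate([profile.mono, profile.oe.ravel()])
    raise ValueError(f"mode must be 'frequencies' or 'oe', got {mode!r}")


FEATURE_NAMES = tuple(NUCLEOTIDES) + DINUCLEOTIDES


# ---------------------------------------------------------------------------
# Canonical discriminant analysis


@dataclass(frozen=True)
class DiscriminantModel:
    """Fitted canonical discriminant analysis.

    ``scalings`` (p x k) maps centered features to canonical coordinates in
    which the pooled within-class covariance is the identity, so Euclidean
    distance in canonical space is Mahalanobis distance in feature space.
    ``eigenvalues`` (k,) are the between/within variance ratios of the
    canonical factors, in decreasing order; k = min(#classes - 1, p).
    """

    classes: tuple[str, ...]
    priors: np.ndarray  # (C,)
    grand_mean: np.ndarray  # (p,)
    class_means: np.ndarray  # (C, p)
    scalings: np.ndarray  # (p, k)
    eigenvalues: np.ndarray  # (k,)
    centroids_canonical: np.ndarray  # (C, k)
    ridge: float
    feature_mode: str | None = None

    @property
    def n_factors(self) -> int:
        return self.scalings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project feature rows into canonical-factor space."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.grand_mean.shape[0]:
            raise DimensionError(
                f"expected {self.grand_mean.shape[0]} features, got {X.shape[1]}"
            )
        return (X - self.grand_mean) @ self.scalings


@dataclass(frozen=True)
class HostPrediction:
    predicted: str
    scores: dict  # label -> canonical-space (Mahalanobis) distance
    canonical_coordinates: np.ndarray


def fit_cda(
    features: np.ndarray,
    labels: Sequence[str],
    ridge: float = 1e-6,
    priors: str = "equal",
    feature_mode: str | None = None,
) -> DiscriminantModel:
    """Fit canonical discriminant axes over labeled feature vectors.

    B (between-class scatter, class-size weighted) is solved against
    W + ridge*trace(W)/p * I (pooled within-class scatter) as a generalized
    symmetric eigenproblem; eigenvectors are rescaled so that the pooled
    within-class covariance in canonical space is the identity, and their
    sign is fixed so the largest-magnitude loading is positive.

    ``priors`` is ``"equal"`` (default — a tiny class can still win) or
    ``"proportional"``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise DataError("features must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise DataError("features contain non-finite values")
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise LabelError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if (counts == 0).any():
        raise LabelError("every class must have at least one member")
    n, p = X.shape
    C = len(classes)
    if C < 2:
        raise LabelError("need at least two classes")
    if n < C + 1:
        raise LabelError(f"need at least {C + 1} observations for {C} classes")

    means = np.vstack([X[y_idx == c].mean(axis=0) for c in range(C)])
    grand = X.mean(axis=0)
    centered = X - means[y_idx]
    W = centered.T @ centered
    dm = means - grand
    B = (counts[:, None] * dm).T @ dm

    eps = ridge * np.trace(W) / p
    Wr = W + eps * np.eye(p)
    evals, evecs = sla.eigh(B, Wr)
    order = np.argsort(evals)[::-1]
    k = min(C - 1, p)
    evals = np.clip(evals[order[:k]], 0.0, None)
    V = evecs[:, order[:k]]
    # eigh normalizes v' Wr v = 1; rescale to unit pooled within-class
    # covariance (Wr / (n - C)) in canonical space.
    V = V * np.sqrt(n - C)
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip

    if priors == "equal":
        pri = np.full(C, 1.0 / C)
    elif priors == "proportional":
        pri = counts / n
    else:
        raise ValueError(f"priors must be 'equal' or 'proportional', got {priors!r}")

    return DiscriminantModel(
        classes=tuple(str(c) for c in classes),
        priors=pri,
        grand_mean=grand,
        class_means=means,
        scalings=V,
        eigenvalues=evals,
        centroids_canonical=(means - grand) @ V,
        ridge=ridge,
        feature_mode=feature_mode,
    )


def classify(model: DiscriminantModel, features: np.ndarray) -> HostPrediction:
    """Nearest class centroid in canonical space (log-prior adjusted)."""
    coords = model.transform(np.asarray(features, dtype=float).reshape(1, -1))[0]
    d = np.linalg.norm(model.centroids_canonical - coords, axis=1)
    penal = 0.5 * d**2 - np.log(model.priors)
    best = int(np.argmin(penal))
    return HostPrediction(
        predicted=model.classes[best],
        scores={c: float(di) for c, di in zip(model.classes, d)},
        canonical_coordinates=coords,
    )


def predict_labels(model: DiscriminantModel, features: np.ndarray) -> np.ndarray:
    """Vectorized nearest-centroid labels for a feature matrix."""
    Z = model.transform(features)
    d2 = ((Z[:, None, :] - model.centroids_canonical[None, :, :]) ** 2).sum(axis=2)
    penal = 0.5 * d2 - np.log(model.priors)[None, :]
    return np.asarray(model.classes)[np.argmin(penal, axis=1)]


def concordance(
    features: np.ndarray,
    labels: Sequence[str],
    scheme: str = "resubstitution",
    ridge: float = 1e-6,
    priors: str = "equal",
) -> float:
    """Fraction of sequences whose predicted host matches its annotation.

    ``resubstitution`` fits once on all data and predicts the same data (the
    optimistic in-sample figure); ``loo`` refits with each sequence held out
    (honest but slower).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if scheme == "resubstitution":
        model = fit_cda(X, y, ridge=ridge, priors=priors)
        return float((predict_labels(model, X) == y).mean())
    if scheme == "loo":
        hits = 0
        idx = np.arange(len(y))
        for i in idx:
            keep = idx != i
            if len(np.unique(y[keep])) < 2:
                raise LabelError("leave-one-out removes an entire class")
            model = fit_cda(X[keep], y[keep], ridge=ridge, priors=priors)
            hits += int(predict_labels(model, X[i : i + 1])[0] == y[i])
        return hits / len(y)
    raise ValueError(f"scheme must be 'resubstitution' or 'loo', got {scheme!r}")


# ---------------------------------------------------------------------------
# Confidence ellipses for canonical-factor scatter plots


@dataclass(frozen=True)
class ConfidenceEllipse:
    """A chi-square confidence ellipse around a 2-D point cloud's centroid.

    ``axes`` are the semi-axis lengths (major first); ``angle`` is the
    orientation of the major axis in radians counter-clockwise from +x.
    """

    center: np.ndarray
    axes: np.ndarray
    angle: float
    level: float
    degenerate: bool = False


def confidence_ellipse(
    points: np.ndarray, level: float = 0.95
) -> ConfidenceEllipse:
    """Ellipse containing ~``level`` of a Gaussian fitted to ``points``.

    Semi-axes are sqrt(eigenvalue * chi2.ppf(level, df=2)) of the 2-D sample
    covariance.  A (near-)singular covariance yields a flagged degenerate
    ellipse rather than an error.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise DataError("points must be n x 2")
    if P.shape[0] < 3:
        raise DataError("need at least 3 points for an ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = P.mean(axis=0)
    cov = np.cov(P, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
    q = chi2.ppf(level, df=2)
    axes = np.sqrt(np.clip(evals, 0.0, None) * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(center, axes, angle, level, degenerate)


# ---------------------------------------------------------------------------
# Model persistence (plain JSON; arrays as nested lists)


def save_model(model: DiscriminantModel, path: str | Path) -> None:
    payload = {
        "classes": list(model.classes),
        "priors": model.priors.tolist(),
        "grand_mean": model.grand_mean.tolist(),
        "class_means": model.class_means.tolist(),
        "scalings": model.scalings.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "centroids_canonical": model.centroids_canonical.tolist(),
        "ridge": model.ridge,
        "feature_mode": model.feature_mode,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> DiscriminantModel:
    d = json.loads(Path(path).read_text())
    return DiscriminantModel(
        classes=tuple(d["classes"]),
        priors=np.asarray(d["priors"]),
        grand_mean=np.asarray(d["grand_mean"]),
        class_means=np.asarray(d["class_means"]),
        scalings=np.asarray(d["scalings"]),
        eigenvalues=np.asarray(d["eigenvalues"]),
        centroids_canonical=np.asarray(d["centroids_canonical"]),
        ridge=float(d["ridge"]),
        feature_mode=d.get("feature_mode"),
    )
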