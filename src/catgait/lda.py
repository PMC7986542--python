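"""The Fisher-discriminant gait index.

The gait index is a fixed linear combination of gait parameters,

    p_LDA = sum_i  w_i  p_i ,

whose weights are the leading eigenvector of the within/between-class
scatter problem of two-group run-level data:

    S_w = sum_j sum_i (x_ij - mu_j)(x_ij - mu_j)^T      (within-class)
    S_b = sum_j (mu_j - mu)(mu_j - mu)^T                (between-class)
    S_w^-1 S_b w = lambda w .

S_b is formed from unweighted group-mean outer products (the ``literal``
convention; the textbook N_j-weighted form is available via
``sb_weighting='nj_weighted'``) and mu is the mean of all runs.  The
fitted direction is normalized so that the anchor parameter (forepaw
swing time for the shipped vector) has weight exactly 1, and oriented so
that the designated positive group (uninjured) scores higher.  Scores are
computed in raw parameter units — the weights absorb scale.

A nine-parameter weight vector derived on pooled uninjured vs thoracic
SCI rat data ships with the package (:func:`published_weights`); higher
index values mean gait closer to uninjured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .features import GroupedFeatureData


@dataclass(frozen=True)
class WeightVector:
    """Ordered parameter names and their weights, with scaling metadata."""

    names: tuple[str, ...]
    weights: np.ndarray
    anchor: str | None = None
    positive_group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if len(self.names) != self.weights.size:
            raise ValueError("names and weights length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def weight(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.names), name="weight")

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if self.anchor:
                fh.write(f"# anchor={self.anchor}\n")
            if self.positive_group:
                fh.write(f"# positive_group={self.positive_group}\n")
            fh.write("parameter,weight\n")
            for n, w in zip(self.names, self.weights):
                fh.write(f"{n},{float(w)!r}\n")

    @classmethod
    def from_csv(cls, path_or_buf) -> "WeightVector":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        meta = {}
        body = []
        for line in lines:
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            elif line.strip():
                body.append(line)
        names, weights = [], []
        for line in body[1:]:  # skip header
            n, _, w = line.partition(",")
            names.append(n.strip())
            weights.append(float(w))
        return cls(
            names=tuple(names),
            weights=np.array(weights),
            anchor=meta.get("anchor"),
            positive_group=meta.get("positive_group"),
        )


@dataclass(frozen=True)
class ScoreResult:
    """One scored feature vector: the index value and per-parameter terms."""

    score: float
    contributions: pd.Series
    identifier: str = ""


@dataclass
class ScatterPair:
    s_w: np.ndarray
    s_b: np.ndarray


@dataclass
class LdaModel:
    """Fitted discriminant: scatter matrices, spectrum and direction."""

    scatter: ScatterPair
    eigenvalues: np.ndarray  # descending
    eigenvector: np.ndarray  # leading, unit norm
    feature_names: tuple[str, ...]
    classes: tuple
    group_means: pd.DataFrame


def published_weights() -> WeightVector:
    """The packaged nine-parameter weight vector (anchor: forepaw swing time)."""
    with resources.files("catgait.data").joinpath("published_weights.csv").open() as fh:
        return WeightVector.from_csv(fh)


def _validate_matrix(data: GroupedFeatureData) -> tuple[np.ndarray, np.ndarray]:
    X = data.features.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = data.features.columns[data.features.isna().any()].tolist()
        rows = data.features.index[data.features.isna().any(axis=1)].tolist()
        raise ValueError(
            f"missing values in scoring columns {bad} (rows {rows}); "
            "drop or complete these runs before the fit"
        )
    return X, np.asarray(data.groups)


def scatter_within(data: GroupedFeatureData) -> np.ndarray:
    """Within-class scatter: sum of outer products of within-group deviations."""
    X, g = _validate_matrix(data)
    s_w = np.zeros((X.shape[1], X.shape[1]))
    for label in pd.unique(g):
        block = X[g == label]
        if block.shape[0] < 2:
            raise ValueError(f"group {label!r} has fewer than 2 runs")
        dev = block - block.mean(axis=0)
        s_w += dev.T @ dev
    return s_w


def scatter_between(data: GroupedFeatureData, weighting: str = "literal") -> np.ndarray:
    """Between-class scatter from group-mean deviations off the overall run mean.

    ``literal`` (default) sums unweighted outer products of (mu_j - mu);
    ``nj_weighted`` multiplies each term by the group size N_j.
    """
    if weighting not in ("literal", "nj_weighted"):
        raise ValueError("weighting must be 'literal' or 'nj_weighted'")
    X, g = _validate_matrix(data)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("between-class scatter needs >=2 groups")
    mu = X.mean(axis=0)
    s_b = np.zeros((X.shape[1], X.shape[1]))
    for label in labels:
        block = X[g == label]
        d = block.mean(axis=0) - mu
        w = block.shape[0] if weighting == "nj_weighted" else 1.0
        s_b += w * np.outer(d, d)
    return s_b


def fit_lda(
    data: GroupedFeatureData,
    sb_weighting: str = "literal",
    ridge: bool = False,
) -> LdaModel:
    """Leading eigenpair of S_w^-1 S_b on run-level data.

    Solved as the symmetric-definite generalized problem S_b w = lambda
    S_w w; eigenvalues are real and non-negative and reported descending.
    A singular S_w raises (with its condition number) unless
    ``ridge=True``, which adds eps I with eps = 1e-8 trace(S_w)/N_p.
    """
    s_w = scatter_within(data)
    s_b = scatter_between(data, weighting=sb_weighting)
    n_p = s_w.shape[0]
    if ridge:
        s_w = s_w + 1e-8 * np.trace(s_w) / n_p * np.eye(n_p)
    cond = np.linalg.cond(s_w)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"within-class scatter is (near-)singular, cond={cond:.3g}; "
            "enable ridge regularization or drop collinear parameters"
        )
    eigvals, eigvecs = linalg.eigh(s_b, s_w)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    w = eigvecs[:, order[0]]
    w = w / np.linalg.norm(w)
    X, g = _validate_matrix(data)
    means = pd.DataFrame(
        {label: X[g == label].mean(axis=0) for label in pd.unique(g)},
        index=list(data.features.columns),
    ).T
    return LdaModel(
        scatter=ScatterPair(s_w=s_w, s_b=s_b),
        eigenvalues=eigvals,
        eigenvector=w,
        feature_names=tuple(data.features.columns),
        classes=tuple(pd.unique(g)),
        group_means=means,
    )


def normalize_weights(
    model: LdaModel, anchor_parameter: str, positive_group
) -> WeightVector:
    """Scale the leading eigenvector to the publishing convention.

    The vector is first oriented so that ``positive_group`` has the higher
    mean score (the eigensolver's sign is arbitrary), then scaled by the
    magnitude of its anchor component, making the anchor weight +1 when the
    anchor parameter itself rises with the positive group — the published
    situation, where uninjured rats have the longer forepaw swing time —
    and -1 otherwise.  Orientation always takes precedence over the anchor
    sign.
    """
    names = model.feature_names
    if anchor_parameter not in names:
        raise ValueError(f"anchor parameter {anchor_parameter!r} not among {names}")
    w = model.eigenvector.copy()
    a = w[names.index(anchor_parameter)]
    if a == 0:
        magnitudes = dict(zip(names, np.abs(w)))
        alt = max(magnitudes, key=magnitudes.get)
        raise ValueError(
            f"anchor {anchor_parameter!r} has zero weight; try anchoring on {alt!r}"
        )
    mean_scores = model.group_means.to_numpy() @ w
    scores = dict(zip(model.classes, mean_scores))
    if positive_group not in scores:
        raise ValueError(f"{positive_group!r} is not one of the fitted groups {model.classes}")
    others = [v for k, v in scores.items() if k != positive_group]
    if scores[positive_group] < max(others):
        w = -w
    w = w / abs(w[names.index(anchor_parameter)])
    return WeightVector(
        names=names, weights=w, anchor=anchor_parameter, positive_group=str(positive_group)
    )


def score(features, weights: WeightVector, identifier: str = "") -> ScoreResult:
    """p_LDA = sum_i w_i p_i for one named feature vector.

    ``features`` is any name -> value mapping (dict, Series, RunFeatures
    values).  Every weighted parameter must be present and finite; missing
    ones are named in the error.
    """
    if hasattr(features, "values") and isinstance(getattr(features, "values"), dict):
        features = features.values  # RunFeatures
    vec = []
    missing = []
    for name in weights.names:
        v = features.get(name) if hasattr(features, "get") else features[name]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing.append(name)
        else:
            vec.append(float(v))
    if missing:
        raise ValueError(f"unscoreable: missing parameters {missing}")
    contributions = pd.Series(
        np.asarray(vec) * weights.weights, index=list(weights.names)
    )
    return ScoreResult(
        score=float(contributions.sum()), contributions=contributions, identifier=identifier
    )


def score_frame(frame: pd.DataFrame, weights: WeightVector) -> pd.Series:
    """Vectorized p_LDA over the rows of a table holding the weighted columns."""
    missing = [n for n in weights.names if n not in frame.columns]
    if missing:
        raise ValueError(f"unscoreable: missing parameter columns {missing}")
    X = frame[list(weights.names)].to_numpy(dtype=float)
    return pd.Series(X @ weights.weights, index=frame.index, name="p_lda")


class GaitIndexScorer(BaseEstimator, TransformerMixin):
    """Apply a fixed weight vector as a transformer.

    ``weights='published'`` (default) uses the packaged nine-parameter
    vector.  ``transform`` accepts a DataFrame carrying the weighted
    columns and returns an (n, 1) array of index values;
    ``score_samples`` returns them as a Series, ``contributions`` as the
    per-parameter terms.
    """

    def __init__(self, weights="published"):
        self.weights = weights

    def _vector(self) -> WeightVector:
        if isinstance(self.weights, WeightVector):
            return self.weights
        if self.weights == "published":
            return published_weights()
        return WeightVector.from_csv(self.weights)

    def fit(self, X=None, y=None):
        self.weight_vector_ = self._vector()
        self.feature_names_in_ = np.asarray(self.weight_vector_.names, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "weight_vector_"):
            self.fit()
        return score_frame(pd.DataFrame(X), self.weight_vector_).to_numpy()[:, None]

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "weight_vector_"):
            self.fit()
        return score_frame(pd.DataFrame(X), self.weight_vector_)

    def contributions(self, X: pd.DataFrame) -> pd.DataFrame:
        wv = self._vector()
        mat = pd.DataFrame(X)[list(wv.names)].to_numpy(dtype=float) * wv.weights
        return pd.DataFrame(mat, columns=list(wv.names), index=pd.DataFrame(X).index)


class GaitIndexLDA(BaseEstimator, TransformerMixin):
    """Fit the discriminant weight vector from two-group run-level data.

    Parameters
    ----------
    anchor_parameter : parameter whose weight is scaled to exactly 1.
    positive_group : group that must score higher (defaults to the first
        label seen in ``y``).
    sb_weighting : 'literal' (unweighted group-mean outer products) or
        'nj_weighted'.
    ridge : add a small multiple of the identity to S_w when it is
        near-singular.

    Attributes (after ``fit``)
    --------------------------
    scatter_within_, scatter_between_ : the scatter matrices.
    eigenvalues_ : real non-negative spectrum, descending.
    eigenvector_ : leading eigenvector, unit norm.
    weights_ : anchored, oriented :class:`WeightVector`.
    classes_, feature_names_in_
    """

    def __init__(
        self,
        anchor_parameter: str = "forepaw_swing_time",
        positive_group=None,
        sb_weighting: str = "literal",
        ridge: bool = False,
    ):
        self.anchor_parameter = anchor_parameter
        self.positive_group = positive_group
        self.sb_weighting = sb_weighting
        self.ridge = ridge

    def fit(self, X, y):
        X = pd.DataFrame(X)
        data = GroupedFeatureData(features=X, groups=pd.Series(list(y)))
        model = fit_lda(data, sb_weighting=self.sb_weighting, ridge=self.ridge)
        positive = self.positive_group if self.positive_group is not None else model.classes[0]
        self.model_ = model
        self.scatter_within_ = model.scatter.s_w
        self.scatter_between_ = model.scatter.s_b
        self.eigenvalues_ = model.eigenvalues
        self.eigenvector_ = model.eigenvector
        self.classes_ = np.asarray(model.classes, dtype=object)
        self.feature_names_in_ = np.asarray(model.feature_names, dtype=object)
        self.weights_ = normalize_weights(model, self.anchor_parameter, positive)
        return self

    def transform(self, X) -> np.ndarray:
        return score_frame(pd.DataFrame(X), self.weights_).to_numpy()[:, None]

    def score_samples(self, X) -> pd.Series:
        return score_frame(pd.DataFrame(X), self.weights_)
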