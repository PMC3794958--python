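"""Incremental PCA+LDA classifier for high-dimensional shape features.

The discrimination problem is two-class (amyloid-positive vs -negative)
with many more features than subjects, so LDA alone is singular. The
classifier first projects onto the principal subspace retaining a
configured fraction of total variance (default 70%), then fits Fisher's
linear discriminant in that subspace:

    w ∝ S_w⁻¹ (μ₊ − μ₋),      score(x) = wᵀ P(x − x̄) − c,

with S_w the pooled within-class scatter, P the PCA projection and c the
midpoint of the projected class means. A score > 0 (ties included) labels
the subject amyloid-positive — a deliberate screening-oriented tie-break.

Incremental learning is exact: the estimator accumulates per-class counts,
sums and second-moment matrices, and re-derives PCA and LDA from those
sufficient statistics after every batch. A model that has absorbed batches
B₁…B_m is therefore prediction-equivalent to one trained on B₁∪…∪B_m in a
single call, for any partition — unlike approximate eigenspace-merging
schemes, the equivalence is a testable contract, feasible because the
spectral feature dimension is at most a few hundred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClassifierMixin

POSITIVE, NEGATIVE = 1, 0


class NotFittedError(RuntimeError):
    pass


@dataclass
class PCAModel:
    """Principal subspace: mean, orthonormal components, variances, and the
    retained dimension d = min{k : cumvar(k) ≥ variance_fraction}."""

    mean: np.ndarray
    components: np.ndarray  # (p, d), columns orthonormal
    variances: np.ndarray  # (d,), non-increasing
    variance_fraction: float

    @property
    def d(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.components


@dataclass
class LDAModel:
    """Fisher discriminant in PCA space: unit axis w, threshold c at the
    midpoint of the projected class means, plus the class statistics."""

    w: np.ndarray
    threshold: float
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    within_scatter: np.ndarray

    def scores(self, Z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(Z) @ self.w - self.threshold


def _fix_signs(components: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(components), axis=0)
    s = np.sign(components[idx, np.arange(components.shape[1])])
    s[s == 0] = 1.0
    return components * s


class PCALDAClassifier(BaseEstimator, ClassifierMixin):
    """PCA (variance-fraction truncated) + LDA with exact incremental updates.

    Parameters
    ----------
    variance_fraction : float in (0, 1], default 0.70
        Retain the smallest number of principal components whose cumulative
        explained-variance fraction reaches this value.
    priors_weighted : bool, default False
        If True, shift the decision threshold by the log-ratio of class
        priors (estimated from training counts); the default midpoint rule
        treats both classes symmetrically regardless of imbalance.

    Attributes (after fit)
    ----------------------
    classes_ : array([0, 1]); 1 is the amyloid-positive class
    pca_ : PCAModel
    lda_ : LDAModel
    n_seen_ : total subjects absorbed
    """

    def __init__(self, variance_fraction: float = 0.70, priors_weighted: bool = False):
        self.variance_fraction = variance_fraction
        self.priors_weighted = priors_weighted

    # -- sufficient statistics ------------------------------------------

    def _reset(self, p: int) -> None:
        self.n_features_in_ = p
        self._counts = {POSITIVE: 0, NEGATIVE: 0}
        self._sums = {POSITIVE: np.zeros(p), NEGATIVE: np.zeros(p)}
        self._sqsums = {POSITIVE: np.zeros((p, p)), NEGATIVE: np.zeros((p, p))}
        self.training_log_ = []

    def _accumulate(self, X: np.ndarray, y: np.ndarray) -> None:
        for cls in (POSITIVE, NEGATIVE):
            Xc = X[y == cls]
            if len(Xc):
                self._counts[cls] += len(Xc)
                self._sums[cls] += Xc.sum(axis=0)
                self._sqsums[cls] += Xc.T @ Xc
        self.training_log_.append(
            {"batch_size": int(len(X)),
             "n_seen": int(self._counts[POSITIVE] + self._counts[NEGATIVE])}
        )

    def _rederive(self) -> None:
        n_pos, n_neg = self._counts[POSITIVE], self._counts[NEGATIVE]
        n = n_pos + n_neg
        if n_pos < 2 or n_neg < 2:
            raise ValueError(
                f"each class needs >= 2 subjects (have {n_pos} positive, "
                f"{n_neg} negative)"
            )
        total_sum = self._sums[POSITIVE] + self._sums[NEGATIVE]
        total_sq = self._sqsums[POSITIVE] + self._sqsums[NEGATIVE]
        mean = total_sum / n
        # total scatter about the global mean
        T = total_sq - np.outer(total_sum, mean) - np.outer(mean, total_sum) \
            + n * np.outer(mean, mean)
        T = (T + T.T) / 2.0
        cov = T / (n - 1)
        evals, evecs = scipy.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        evals = np.maximum(evals, 0.0)
        total_var = evals.sum()
        if total_var <= 0:
            raise ValueError("zero total variance in training data")
        cum = np.cumsum(evals) / total_var
        vf = min(self.variance_fraction, 1.0)
        if not 0 < vf <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        # effective rank cap so components with ~zero variance are dropped
        rank = int(np.sum(evals > 1e-10 * evals[0]))
        d = int(np.searchsorted(cum, vf - 1e-9) + 1)
        d = min(d, rank)
        C = _fix_signs(evecs[:, :d])
        self.pca_ = PCAModel(mean, C, evals[:d], vf)

        # per-class statistics in PCA space
        mu = {c: self._sums[c] / self._counts[c] for c in (POSITIVE, NEGATIVE)}
        mu_z = {c: (mu[c] - mean) @ C for c in (POSITIVE, NEGATIVE)}
        Sw = np.zeros((d, d))
        for c in (POSITIVE, NEGATIVE):
            # class scatter about its own mean, projected
            Sc = self._sqsums[c] - np.outer(self._sums[c], mu[c]) \
                 - np.outer(mu[c], self._sums[c]) \
                 + self._counts[c] * np.outer(mu[c], mu[c])
            Sw += C.T @ ((Sc + Sc.T) / 2.0) @ C
        Sw = (Sw + Sw.T) / 2.0
        dmu = mu_z[POSITIVE] - mu_z[NEGATIVE]
        try:
            w = scipy.linalg.solve(Sw / (n - 2), dmu, assume_a="pos")
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
            raise ValueError(
                "singular pooled within-class scatter; lower the PCA "
                "variance_fraction to reduce the subspace dimension"
            ) from exc
        nw = np.linalg.norm(w)
        if not np.isfinite(nw) or nw == 0:
            raise ValueError(
                "degenerate LDA axis; lower the PCA variance_fraction"
            )
        w = w / nw
        c_mid = 0.5 * (w @ mu_z[POSITIVE] + w @ mu_z[NEGATIVE])
        if self.priors_weighted:
            # shift by log prior odds scaled by the projected within-class
            # variance (Gaussian equal-covariance decision rule)
            s2 = float(w @ (Sw / (n - 2)) @ w)
            gap = float(w @ mu_z[POSITIVE] - w @ mu_z[NEGATIVE])
            if gap > 0:
                c_mid -= s2 / gap * np.log(n_pos / n_neg)
        self.lda_ = LDAModel(w, c_mid, mu_z[POSITIVE], mu_z[NEGATIVE], Sw)
        self.classes_ = np.array([NEGATIVE, POSITIVE])
        self.n_seen_ = n

    # -- sklearn API -----------------------------------------------------

    @staticmethod
    def _check_Xy(X, y):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y).ravel().astype(int)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if not np.all(np.isin(y, [NEGATIVE, POSITIVE])):
            raise ValueError("labels must be 0 (PiB-) or 1 (PiB+)")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        return X, y

    def fit(self, X, y):
        """Batch training: reset accumulators, absorb all data, derive."""
        X, y = self._check_Xy(X, y)
        self._reset(X.shape[1])
        self._accumulate(X, y)
        self._rederive()
        return self

    def partial_fit(self, X, y, classes=None):
        """Absorb one batch and re-derive PCA+LDA from the accumulated
        sufficient statistics (exact incremental learning)."""
        X, y = self._check_Xy(X, y)
        if len(X) == 0:
            raise ValueError("empty batch")
        if not hasattr(self, "_counts"):
            self._reset(X.shape[1])
        elif X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} != state's {self.n_features_in_}"
            )
        self._accumulate(X, y)
        # a model only exists once both classes have >= 2 subjects; until
        # then keep accumulating without deriving
        if min(self._counts.values()) >= 2:
            self._rederive()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "lda_"):
            raise NotFittedError("classifier is not trained")

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, float))
        return self.lda_.scores(self.pca_.transform(X))

    def predict(self, X) -> np.ndarray:
        """Labels: positive iff score >= 0 (ties go to the positive class)."""
        return np.where(self.decision_function(X) >= 0, POSITIVE, NEGATIVE)

    # -- introspection ---------------------------------------------------

    @property
    def feature_axis_(self) -> np.ndarray:
        """LDA axis back in feature space (PCA components @ w), unnormalized."""
        self._check_fitted()
        return self.pca_.components @ self.lda_.w

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the full state (version-tagged)."""
        self._check_fitted()
        return {
            "format_version": 1,
            "variance_fraction": self.variance_fraction,
            "priors_weighted": self.priors_weighted,
            "counts": {str(k): int(v) for k, v in self._counts.items()},
            "sums": {str(k): v.tolist() for k, v in self._sums.items()},
            "sqsums": {str(k): v.tolist() for k, v in self._sqsums.items()},
            "training_log": self.training_log_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCALDAClassifier":
        if d.get("format_version") != 1:
            raise ValueError("unknown classifier state version")
        obj = cls(d["variance_fraction"], d["priors_weighted"])
        p = len(next(iter(d["sums"].values())))
        obj._reset(p)
        obj._counts = {int(k): int(v) for k, v in d["counts"].items()}
        obj._sums = {int(k): np.asarray(v, float) for k, v in d["sums"].items()}
        obj._sqsums = {int(k): np.asarray(v, float) for k, v in d["sqsums"].items()}
        obj.training_log_ = list(d["training_log"])
        obj._rederive()
        return obj


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator


def fit_pca(X, variance_fraction: float = 0.70) -> PCAModel:
    """PCA retaining the minimal dimension reaching the variance fraction."""
    X = np.atleast_2d(np.asarray(X, float))
    if len(X) < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (len(X) - 1)
    evals, evecs = scipy.linalg.eigh(cov)
    evals, evecs = np.maximum(evals[::-1], 0.0), evecs[:, ::-1]
    total = evals.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    cum = np.cumsum(evals) / total
    rank = int(np.sum(evals > 1e-10 * evals[0]))
    d = min(int(np.searchsorted(cum, variance_fraction - 1e-9) + 1), rank)
    return PCAModel(mean, _fix_signs(evecs[:, :d]), evals[:d], variance_fraction)


def fit_lda(Z, y) -> LDAModel:
    """Fisher LDA on already-reduced features: w ∝ S_w⁻¹(μ₊ − μ₋), unit
    norm; threshold at the midpoint of the projected class means."""
    Z = np.atleast_2d(np.asarray(Z, float))
    yv = np.asarray(y).ravel().astype(int)
    for cls in (NEGATIVE, POSITIVE):
        if np.sum(yv == cls) < 2:
            raise ValueError(f"class {cls} needs >= 2 subjects")
    mu_p, mu_n = Z[yv == POSITIVE].mean(0), Z[yv == NEGATIVE].mean(0)
    Sw = sum(
        (Z[yv == k] - Z[yv == k].mean(0)).T @ (Z[yv == k] - Z[yv == k].mean(0))
        for k in (NEGATIVE, POSITIVE)
    )
    Sw = (Sw + Sw.T) / 2.0
    try:
        w = scipy.linalg.solve(Sw / (len(Z) - 2), mu_p - mu_n, assume_a="pos")
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "singular within-class scatter; reduce dimensionality (PCA)"
        ) from exc
    w = w / np.linalg.norm(w)
    c = 0.5 * float(w @ mu_p + w @ mu_n)
    return LDAModel(w, c, mu_p, mu_n, Sw)


def train_batch(X, y, variance_fraction: float = 0.70) -> PCALDAClassifier:
    return PCALDAClassifier(variance_fraction).fit(X, y)


def update_incremental(state: PCALDAClassifier, X, y) -> PCALDAClassifier:
    return state.partial_fit(X, y)


def predict_subject(state: PCALDAClassifier, feature) -> tuple:
    """(label, decision score) for one subject's feature vector."""
    values = getattr(feature, "values", feature)
    score = float(state.decision_function(np.atleast_2d(values))[0])
    return (POSITIVE if score >= 0 else NEGATIVE), score
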