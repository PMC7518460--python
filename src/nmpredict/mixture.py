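"""Two-component tied-covariance Gaussian mixture for nucleomorph calling.

Each clustered transcript carries three features: GC1, GC3 and ln TPM.  After
per-feature z-scoring (population standard deviation, denominator n), a
k = 2 Gaussian mixture with a single covariance matrix shared by both
components ("tied") is fit by expectation-maximization, implemented here in
log space:

  E-step   log r_ik = log w_k + log N(x_i | mu_k, Sigma) - logsumexp_k(...)
  M-step   w_k  = mean_i r_ik
           mu_k = sum_i r_ik x_i / sum_i r_ik
           Sigma = (1/n) sum_k sum_i r_ik (x_i - mu_k)(x_i - mu_k)^T + reg I

EM is restarted from ``n_init`` random responsibility draws and the run with
the best final log-likelihood is kept; convergence is declared when the mean
per-point log-likelihood improves by less than ``tol`` between iterations.

The component whose de-standardized mean GC3 is lower is the putative
nucleomorph ("low-GC") component — GC3 being the least constrained and hence
most diagnostic position — with ties broken on mean GC1.  A transcript is
called an Nm-candidate when its posterior for that component is strictly
greater than the threshold (default 0.95).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .errors import (
    AmbiguousModelError,
    DegenerateInputError,
    InvalidInputError,
    NumericalFailureError,
)

FEATURE_NAMES = ("gc1", "gc3", "ln_tpm")
DEFAULT_POSTERIOR_THRESHOLD = 0.95


@dataclass(frozen=True)
class FeatureVector:
    transcript_id: str
    gc1: float
    gc3: float
    ln_tpm: float

    def __post_init__(self) -> None:
        values = (self.gc1, self.gc3, self.ln_tpm)
        if not all(np.isfinite(values)):
            raise InvalidInputError(f"non-finite feature for {self.transcript_id!r}: {values}")


def feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    return np.array([[f.gc1, f.gc3, f.ln_tpm] for f in features], dtype=float)


@dataclass(frozen=True)
class Standardization:
    """Per-feature location/scale of the z-scoring, kept for inverse transforms."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.sd + self.mean


def standardize(
    X: np.ndarray, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> tuple[np.ndarray, Standardization]:
    """Column-wise z-score with population (1/n) standard deviation."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidInputError("standardize requires a 2-D matrix with n >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("non-finite values in feature matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0: population sd
    for j, s in enumerate(sd):
        if s == 0:
            name = feature_names[j] if j < len(feature_names) else f"column {j}"
            raise DegenerateInputError(f"feature {name!r} is constant; cannot standardize")
    std = Standardization(mean=mean, sd=sd)
    return std.transform(X), std


@dataclass
class MixtureModel:
    """A fitted k=2 tied-covariance Gaussian mixture on standardized features."""

    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2, d)
    covariance: np.ndarray  # (d, d), shared
    log_likelihood: float  # total over points
    n_iter: int
    converged: bool
    seed: int | None = None
    log_likelihood_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.weights)

    def to_dict(self, std: Standardization | None = None) -> dict:
        d = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariance": self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
        }
        if std is not None:
            d["standardization"] = {"mean": std.mean.tolist(), "sd": std.sd.tolist()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> tuple["MixtureModel", Standardization | None]:
        model = cls(
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            covariance=np.array(d["covariance"]),
            log_likelihood=float(d["log_likelihood"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            seed=d.get("seed"),
        )
        std = None
        if "standardization" in d:
            s = d["standardization"]
            std = Standardization(mean=np.array(s["mean"]), sd=np.array(s["sd"]))
        return model, std

    def save(self, path: str | Path, std: Standardization | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(std), indent=2) + "\n")


def _gaussian_logpdf(X: np.ndarray, mean: np.ndarray, chol: np.ndarray, log_det: float) -> np.ndarray:
    """Multivariate normal log-density from a precomputed Cholesky factor."""
    d = X.shape[1]
    z = np.linalg.solve(chol, (X - mean).T)  # chol @ z = (x - mu)
    maha = np.sum(z * z, axis=0)
    return -0.5 * (d * np.log(2.0 * np.pi) + log_det + maha)


def _component_log_densities(X: np.ndarray, means: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailureError("tied covariance is not positive definite") from exc
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    return np.column_stack([_gaussian_logpdf(X, mu, chol, log_det) for mu in means])


def _log_responsibilities(
    X: np.ndarray, weights: np.ndarray, means: np.ndarray, covariance: np.ndarray
) -> tuple[np.ndarray, float]:
    """(log responsibilities, total log-likelihood) in one E-step."""
    weighted = _component_log_densities(X, means, covariance) + np.log(weights)
    norm = logsumexp(weighted, axis=1)
    return weighted - norm[:, None], float(norm.sum())


def _m_step(
    X: np.ndarray, resp: np.ndarray, reg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    nk = resp.sum(axis=0)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covariance = np.zeros((d, d))
    for j in range(resp.shape[1]):
        centered = X - means[j]
        covariance += (resp[:, j, None] * centered).T @ centered
    covariance = covariance / n + reg * np.eye(d)
    return weights, means, covariance


def em_fit(
    Xs: np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float = 1e-6,
) -> MixtureModel:
    """Fit the tied-covariance mixture by EM, best of ``n_init`` seeded restarts."""
    Xs = np.asarray(Xs, dtype=float)
    if not np.all(np.isfinite(Xs)):
        raise InvalidInputError("non-finite values in standardized matrix")
    n, d = Xs.shape
    if n <= k:
        raise InvalidInputError(f"need more points ({n}) than components ({k})")
    rng = np.random.default_rng(seed)
    best: MixtureModel | None = None
    for _ in range(n_init):
        # Seeded random restart: k distinct data points as initial means.
        # (Per-point random responsibilities average out to the pooled mean
        # for both components and strand EM on the symmetric saddle, where
        # the likelihood gain per iteration is already below any usable tol.)
        idx = rng.choice(n, size=k, replace=False)
        means = Xs[idx].copy()
        weights = np.full(k, 1.0 / k)
        covariance = np.cov(Xs, rowvar=False, bias=True) + reg * np.eye(d)
        history: list[float] = []
        prev_mean_ll = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            log_resp, total_ll = _log_responsibilities(Xs, weights, means, covariance)
            history.append(total_ll)
            mean_ll = total_ll / n
            if mean_ll - prev_mean_ll < tol:
                converged = True
                break
            prev_mean_ll = mean_ll
            weights, means, covariance = _m_step(Xs, np.exp(log_resp), reg)
        candidate = MixtureModel(
            weights=weights,
            means=means,
            covariance=covariance,
            log_likelihood=history[-1],
            n_iter=n_iter,
            converged=converged,
            seed=seed,
            log_likelihood_history=history,
        )
        if best is None or candidate.log_likelihood > best.log_likelihood:
            best = candidate
    assert best is not None
    return best


def posterior(model: MixtureModel, Xs: np.ndarray) -> np.ndarray:
    """n x k responsibility matrix via Bayes rule on Gaussian log-densities."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    log_resp, _ = _log_responsibilities(Xs, model.weights, model.means, model.covariance)
    return np.exp(log_resp)


def identify_low_gc_component(model: MixtureModel, std: Standardization) -> int:
    """Index of the component with the lower de-standardized mean GC3 (tie: GC1).

    Assumes the feature order (gc1, gc3, ln_tpm) used throughout the pipeline.
    """
    means = std.inverse(model.means)
    gc3 = means[:, 1]
    gc1 = means[:, 0]
    order = sorted(range(model.k), key=lambda j: (gc3[j], gc1[j]))
    lo, hi = order[0], order[1]
    if gc3[lo] == gc3[hi] and gc1[lo] == gc1[hi]:
        raise AmbiguousModelError("components have identical mean GC3 and GC1")
    return lo


@dataclass(frozen=True)
class CandidateCall:
    transcript_id: str
    posterior_low_gc: float
    is_nm_candidate: bool


def call_nm_candidates(
    posteriors: np.ndarray,
    low_idx: int,
    transcript_ids: list[str],
    threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
) -> list[CandidateCall]:
    """Nm-candidate calls: posterior for the low-GC component strictly > threshold."""
    if not 0.5 < threshold < 1.0:
        raise InvalidInputError(f"threshold must lie in (0.5, 1), got {threshold}")
    p = np.asarray(posteriors)[:, low_idx]
    return [
        CandidateCall(tid, float(pi), bool(pi > threshold))
        for tid, pi in zip(transcript_ids, p)
    ]
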