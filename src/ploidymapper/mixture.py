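"""K-component Gaussian mixtures in log2 feature space.

Expectation-maximization is implemented in-repo (E-step responsibilities,
per-family M-steps, restart logic) so the per-iteration log-likelihood trace
and the free-parameter count are directly testable.  Four covariance families
are supported:

* ``spherical`` — one variance per component,
* ``diagonal``  — one diagonal covariance per component,
* ``full``      — one general covariance per component,
* ``tied``      — a single general covariance shared by all components.

Model selection scans a grid of component counts and families and ranks the
fits by AIC and BIC (natural-log likelihoods)::

    aic = -2 * log_likelihood + 2 * d
    bic = -2 * log_likelihood + ln(n) * d

where ``d`` is the number of free parameters and ``n`` the sample count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger(__name__)

#: Family order used for tie-breaking in model scans (parsimony first).
FAMILIES: tuple[str, ...] = ("spherical", "diagonal", "full", "tied")

_LOG_2PI = math.log(2.0 * math.pi)


class MixtureFitError(RuntimeError):
    """Raised when a mixture fit cannot be completed."""


class _ComponentCollapse(Exception):
    """Internal: a component collapsed during one EM restart."""


@dataclass
class FitParams:
    """EM hyperparameters.

    Published defaults: 1D fits use ``tol=1e-5``, ``max_iter=10000``,
    ``n_init=20``; 2D fits use ``tol=1e-7``, ``max_iter=5000``,
    ``n_init=500``; both with k-means++-style seeding.  ``tol`` applies to
    the improvement of the mean per-sample log-likelihood.  The seed default
    is fixed (0) for reproducibility.
    """

    tol: float = 1e-5
    max_iter: int = 10000
    n_init: int = 20
    init_method: str = "k-means++"
    seed: int = 0
    reg_covar: float = 1e-6

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.init_method not in ("k-means++", "random"):
            raise ValueError(f"unknown init_method {self.init_method!r}")

    @classmethod
    def defaults_for(cls, n_features: int, **overrides) -> "FitParams":
        """Published defaults for a given feature dimensionality."""
        if n_features <= 1:
            base = dict(tol=1e-5, max_iter=10000, n_init=20)
        else:
            base = dict(tol=1e-7, max_iter=5000, n_init=500)
        base.update(overrides)
        return cls(**base)


def n_free_parameters(K: int, D: int, family: str) -> int:
    """Count of free parameters d: (K-1) weights + K*D means + covariances."""
    if family == "spherical":
        cov = K
    elif family == "diagonal":
        cov = K * D
    elif family == "full":
        cov = K * D * (D + 1) // 2
    elif family == "tied":
        cov = D * (D + 1) // 2
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    return (K - 1) + K * D + cov


def information_criteria(
    log_likelihood: float, d: int, n: int
) -> tuple[float, float]:
    """AIC and BIC from a natural-log likelihood, parameter count and n."""
    aic = -2.0 * log_likelihood + 2.0 * d
    bic = -2.0 * log_likelihood + math.log(n) * d
    return aic, bic


@dataclass
class MixtureModel:
    """A fitted K-component Gaussian mixture in log2 feature space."""

    K: int
    family: str
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, D)
    covariances: np.ndarray  # family-shaped
    log_likelihood: float  # total, natural log
    n: int
    d: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    ll_trace: list[float] = field(default_factory=list)
    feature_names: Optional[list[str]] = None
    seed: Optional[int] = None

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def component_log_prob(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of log wk + log N(x | mu_k, Sigma_k)."""
        X = _as_matrix(X, self.n_features)
        return _log_gaussian_prob(
            X, self.means, self.covariances, self.family
        ) + np.log(self.weights)[None, :]

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Per-sample log density under the mixture."""
        return logsumexp(self.component_log_prob(X), axis=1)

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        """(n, K) responsibilities; each row sums to 1."""
        weighted = self.component_log_prob(X)
        log_norm = logsumexp(weighted, axis=1)
        return np.exp(weighted - log_norm[:, None])


def posteriors(model: MixtureModel, X: np.ndarray) -> np.ndarray:
    """Responsibility matrix of ``model`` for samples ``X`` (rows sum to 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} feature(s), model expects {model.n_features}"
        )
    return model.posteriors(X)


# ---------------------------------------------------------------------------
# EM internals


def _as_matrix(X: np.ndarray, n_features: Optional[int] = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"X must be 1D or 2D, got shape {X.shape}")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(
            f"X has {X.shape[1]} feature(s), expected {n_features}"
        )
    return X


def _log_gaussian_prob(
    X: np.ndarray, means: np.ndarray, covariances: np.ndarray, family: str
) -> np.ndarray:
    """(n, K) log N(x | mu_k, Sigma_k) for each covariance family."""
    n, D = X.shape
    K = means.shape[0]
    if family == "spherical":
        var = covariances  # (K,)
        sq = (
            (X * X).sum(axis=1)[:, None]
            - 2.0 * X @ means.T
            + (means * means).sum(axis=1)[None, :]
        )
        return -0.5 * (D * _LOG_2PI + D * np.log(var)[None, :] + sq / var[None, :])
    if family == "diagonal":
        var = covariances  # (K, D)
        precision = 1.0 / var
        term = (
            (X * X) @ precision.T
            - 2.0 * X @ (means * precision).T
            + ((means * means) * precision).sum(axis=1)[None, :]
        )
        log_det = np.log(var).sum(axis=1)
        return -0.5 * (D * _LOG_2PI + log_det[None, :] + term)
    if family == "full":
        out = np.empty((n, K))
        for k in range(K):
            out[:, k] = _log_gaussian_one(X, means[k], covariances[k])
        return out
    if family == "tied":
        chol = cholesky(covariances, lower=True)
        log_det = 2.0 * np.log(np.diag(chol)).sum()
        out = np.empty((n, K))
        for k in range(K):
            y = solve_triangular(chol, (X - means[k]).T, lower=True)
            out[:, k] = -0.5 * (D * _LOG_2PI + log_det + (y * y).sum(axis=0))
        return out
    raise ValueError(f"unknown covariance family {family!r}")


def _log_gaussian_one(
    X: np.ndarray, mean: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    D = X.shape[1]
    chol = cholesky(cov, lower=True)
    log_det = 2.0 * np.log(np.diag(chol)).sum()
    y = solve_triangular(chol, (X - mean).T, lower=True)
    return -0.5 * (D * _LOG_2PI + log_det + (y * y).sum(axis=0))


def _m_step(
    X: np.ndarray, resp: np.ndarray, family: str, reg_covar: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, D = X.shape
    Nk = resp.sum(axis=0)
    if np.any(Nk < n * 1e-12) or not np.all(np.isfinite(Nk)):
        raise _ComponentCollapse
    weights = Nk / n
    means = (resp.T @ X) / Nk[:, None]
    if family in ("spherical", "diagonal"):
        avg_sq = (resp.T @ (X * X)) / Nk[:, None]
        diag = avg_sq - means * means + reg_covar
        covariances = diag.mean(axis=1) if family == "spherical" else diag
        if np.any(covariances <= 0):
            raise _ComponentCollapse
    elif family == "full":
        K = means.shape[0]
        covariances = np.empty((K, D, D))
        eye = reg_covar * np.eye(D)
        for k in range(K):
            diff = X - means[k]
            covariances[k] = (resp[:, k][:, None] * diff).T @ diff / Nk[k] + eye
    elif family == "tied":
        scatter = X.T @ X - (Nk[:, None] * means).T @ means
        covariances = scatter / n + reg_covar * np.eye(D)
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    return weights, means, covariances


def _init_responsibilities(
    X: np.ndarray, K: int, init_method: str, seed: int
) -> np.ndarray:
    n = X.shape[0]
    if init_method == "k-means++":
        centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed)
    else:
        rng = np.random.default_rng(seed)
        centers = X[rng.choice(n, size=K, replace=False)]
    dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    resp = np.zeros((n, K))
    resp[np.arange(n), dist.argmin(axis=1)] = 1.0
    return resp


def _em_single(
    X: np.ndarray, K: int, family: str, params: FitParams, seed: int
) -> tuple:
    n = X.shape[0]
    resp = _init_responsibilities(X, K, params.init_method, seed)
    weights, means, covariances = _m_step(X, resp, family, params.reg_covar)
    trace: list[float] = []
    prev_mean_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        try:
            weighted = _log_gaussian_prob(X, means, covariances, family) + np.log(
                weights
            )[None, :]
        except np.linalg.LinAlgError as exc:
            raise _ComponentCollapse from exc
        log_norm = logsumexp(weighted, axis=1)
        mean_ll = float(log_norm.mean())
        if not np.isfinite(mean_ll):
            raise _ComponentCollapse
        trace.append(mean_ll * n)
        if abs(mean_ll - prev_mean_ll) < params.tol:
            converged = True
            break
        prev_mean_ll = mean_ll
        resp = np.exp(weighted - log_norm[:, None])
        weights, means, covariances = _m_step(X, resp, family, params.reg_covar)
    if not converged:
        # parameters are one M-step ahead of the last trace entry; re-score
        # so the stored model and its likelihood correspond
        weighted = _log_gaussian_prob(X, means, covariances, family) + np.log(
            weights
        )[None, :]
        trace.append(float(logsumexp(weighted, axis=1).sum()))
    return weights, means, covariances, trace[-1], trace, n_iter, converged


def fit_mixture(
    X: np.ndarray,
    K: int,
    family: str = "spherical",
    params: Optional[FitParams] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> MixtureModel:
    """Fit a K-component Gaussian mixture by EM with random restarts.

    The best model over ``params.n_init`` restarts (by final log-likelihood)
    is returned; within one restart the total log-likelihood is
    non-decreasing over EM iterations (up to ``reg_covar`` effects).  A
    restart whose component collapses is discarded; the fit fails only if
    every restart collapses.  Fits are bit-reproducible for a fixed seed.
    """
    X = _as_matrix(X)
    n, D = X.shape
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")
    if K < 1:
        raise MixtureFitError(f"K must be >= 1, got {K}")
    if n <= K:
        raise MixtureFitError(f"need n > K samples, got n={n}, K={K}")
    if params is None:
        params = FitParams.defaults_for(D)

    seed_seq = np.random.SeedSequence(params.seed)
    restart_seeds = [int(s.generate_state(1)[0]) for s in seed_seq.spawn(params.n_init)]

    best = None
    n_collapsed = 0
    for restart_seed in restart_seeds:
        try:
            result = _em_single(X, K, family, params, restart_seed)
        except _ComponentCollapse:
            n_collapsed += 1
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise MixtureFitError(
            f"all {params.n_init} restart(s) collapsed for K={K}, "
            f"family={family}"
        )
    if n_collapsed:
        logger.debug(
            "fit_mixture(K=%d, %s): %d of %d restarts collapsed",
            K, family, n_collapsed, params.n_init,
        )
    weights, means, covariances, ll, trace, n_iter, converged = best
    d = n_free_parameters(K, D, family)
    aic, bic = information_criteria(ll, d, n)
    return MixtureModel(
        K=K,
        family=family,
        weights=weights,
        means=means,
        covariances=covariances,
        log_likelihood=ll,
        n=n,
        d=d,
        aic=aic,
        bic=bic,
        converged=converged,
        n_iter=n_iter,
        ll_trace=trace,
        feature_names=list(feature_names) if feature_names is not None else None,
        seed=params.seed,
    )


# ---------------------------------------------------------------------------
# Model scan


@dataclass
class ModelSelectionResult:
    """Grid of fits over (K, family) with AIC/BIC ranking."""

    fits: dict  # (K, family) -> MixtureModel or None if that cell failed
    K_values: list[int]
    families: list[str]
    best_by_aic: tuple[int, str]
    best_by_bic: tuple[int, str]
    aic_curve: dict  # family -> list of aic over K (NaN where failed)
    bic_curve: dict
    monotonic_aic: bool
    monotonic_bic: bool
    warnings: list[str] = field(default_factory=list)

    def best(self, criterion: str = "bic") -> MixtureModel:
        coords = self.best_by_bic if criterion == "bic" else self.best_by_aic
        return self.fits[coords]

    @property
    def criteria_disagree(self) -> bool:
        return self.best_by_aic != self.best_by_bic


def _family_order(families: Sequence[str]) -> list[str]:
    return [f for f in FAMILIES if f in set(families)]


def model_scan(
    X: np.ndarray,
    K_range: Iterable[int],
    families: Sequence[str] = ("spherical",),
    params: Optional[FitParams] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> ModelSelectionResult:
    """Fit every (K, family) cell with identical params and rank by AIC/BIC.

    Ties break toward smaller K, then by family order spherical < diagonal <
    full < tied.  When a criterion strictly decreases across the whole
    scanned K range (no interior minimum), the corresponding monotonic flag
    is set and a warning is logged: the chosen K is then a scan-boundary
    artifact and a ploidy ceiling is being assumed.
    """
    X = _as_matrix(X)
    K_values = sorted(set(int(k) for k in K_range))
    if not K_values:
        raise MixtureFitError("K_range is empty")
    if max(K_values) >= X.shape[0]:
        raise MixtureFitError(
            f"max K ({max(K_values)}) must be < n ({X.shape[0]})"
        )
    families = _family_order(families)
    if not families:
        raise ValueError("no known covariance family requested")
    if params is None:
        params = FitParams.defaults_for(X.shape[1])

    fits: dict = {}
    warnings: list[str] = []
    for K in K_values:
        for family in families:
            try:
                fits[(K, family)] = fit_mixture(
                    X, K, family, params, feature_names=feature_names
                )
            except MixtureFitError as exc:
                fits[(K, family)] = None
                msg = f"fit failed for K={K}, family={family}: {exc}"
                warnings.append(msg)
                logger.warning(msg)
    if all(model is None for model in fits.values()):
        raise MixtureFitError("every cell of the model scan failed")

    def argmin(criterion: str) -> tuple[int, str]:
        best_coords, best_value = None, np.inf
        for K in K_values:  # ascending K, then family order: ties keep first
            for family in families:
                model = fits[(K, family)]
                if model is None:
                    continue
                value = getattr(model, criterion)
                if value < best_value:
                    best_coords, best_value = (K, family), value
        return best_coords

    best_by_aic = argmin("aic")
    best_by_bic = argmin("bic")

    curves = {}
    for criterion in ("aic", "bic"):
        curves[criterion] = {
            family: [
                getattr(fits[(K, family)], criterion)
                if fits[(K, family)] is not None
                else float("nan")
                for K in K_values
            ]
            for family in families
        }

    def monotonic(criterion: str, coords: tuple[int, str]) -> bool:
        curve = np.asarray(curves[criterion][coords[1]], dtype=float)
        curve = curve[np.isfinite(curve)]
        return len(curve) > 1 and bool(np.all(np.diff(curve) < 0))

    monotonic_aic = monotonic("aic", best_by_aic)
    monotonic_bic = monotonic("bic", best_by_bic)
    for name, flag in (("AIC", monotonic_aic), ("BIC", monotonic_bic)):
        if flag:
            msg = (
                f"{name} decreases monotonically over the scanned K range "
                f"{K_values[0]}..{K_values[-1]}; the selected K is the scan "
                f"ceiling — a maximum ploidy is being assumed"
            )
            warnings.append(msg)
            logger.warning(msg)
    if best_by_aic != best_by_bic:
        msg = (
            f"AIC and BIC disagree: AIC selects {best_by_aic}, "
            f"BIC selects {best_by_bic}"
        )
        warnings.append(msg)
        logger.warning(msg)

    return ModelSelectionResult(
        fits=fits,
        K_values=K_values,
        families=list(families),
        best_by_aic=best_by_aic,
        best_by_bic=best_by_bic,
        aic_curve=curves["aic"],
        bic_curve=curves["bic"],
        monotonic_aic=monotonic_aic,
        monotonic_bic=monotonic_bic,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Serialization


def model_to_json(model: MixtureModel) -> dict:
    """JSON-serializable document for exact reloading of a fitted model."""
    return {
        "K": model.K,
        "family": model.family,
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": np.asarray(model.covariances).tolist(),
        "log_likelihood": model.log_likelihood,
        "n": model.n,
        "d": model.d,
        "aic": model.aic,
        "bic": model.bic,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "ll_trace": list(model.ll_trace),
        "feature_names": model.feature_names,
        "seed": model.seed,
    }


def model_from_json(doc: dict) -> MixtureModel:
    return MixtureModel(
        K=int(doc["K"]),
        family=doc["family"],
        weights=np.asarray(doc["weights"], dtype=float),
        means=np.asarray(doc["means"], dtype=float),
        covariances=np.asarray(doc["covariances"], dtype=float),
        log_likelihood=float(doc["log_likelihood"]),
        n=int(doc["n"]),
        d=int(doc["d"]),
        aic=float(doc["aic"]),
        bic=float(doc["bic"]),
        converged=bool(doc["converged"]),
        n_iter=int(doc["n_iter"]),
        ll_trace=[float(v) for v in doc.get("ll_trace", [])],
        feature_names=doc.get("feature_names"),
        seed=doc.get("seed"),
    )
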