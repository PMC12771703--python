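"""Finite mixture model for mixed continuous/categorical baseline data.

The model is the latent-class convention for mixed-type clinical tables:
each patient belongs to one of K latent phenotypes with prior weights
``pi_k``; within a phenotype the features are conditionally independent,
continuous features Gaussian with component-specific mean and variance,
binary/categorical features multinomial with component-specific level
probabilities.  The observed-data density is the weighted sum

    h(y) = sum_k pi_k f_k(y | theta_k)

and parameters are fitted by EM with multiple restarts.  The number of
components is chosen by a BIC grid search with an elbow rule: BIC is
``-2 log L + p log n`` (lower is better) and the search stops at the first
K whose next BIC decrease is a small fraction of the initial decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "MixtureParams",
    "MixedMixture",
    "KSelectionTable",
    "e_step",
    "m_step",
    "bic_score",
    "select_k",
    "assign_clusters",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


@dataclass
class MixtureParams:
    """Full parameter bundle: mixing weights plus per-component densities."""

    weights: np.ndarray                    # (K,)
    means: np.ndarray                      # (K, p_cont)
    variances: np.ndarray                  # (K, p_cont)
    category_probs: list[np.ndarray]       # per categorical feature: (K, L_j)
    continuous_names: list[str] = field(default_factory=list)
    categorical_names: list[str] = field(default_factory=list)
    levels: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_free_params(self) -> int:
        """(K-1) weights + per component: mean+variance per continuous
        feature and (levels-1) probabilities per categorical feature."""
        K = self.n_components
        p_cont = self.means.shape[1] if self.means.ndim == 2 else 0
        p_cat = sum(probs.shape[1] - 1 for probs in self.category_probs)
        return (K - 1) + K * (2 * p_cont + p_cat)

    def validate(self, atol: float = 1e-10) -> None:
        if abs(self.weights.sum() - 1.0) > atol:
            raise ValueError("mixing weights do not sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("negative mixing weight")
        if self.means.size and np.any(self.variances <= 0):
            raise ValueError("non-positive variance")
        for j, probs in enumerate(self.category_probs):
            if np.any(np.abs(probs.sum(axis=1) - 1.0) > atol):
                raise ValueError(f"categorical feature {j}: probabilities do not sum to 1")

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "continuous": {
                name: {"mean": self.means[:, j].tolist(), "variance": self.variances[:, j].tolist()}
                for j, name in enumerate(self.continuous_names)
            },
            "categorical": {
                name: {
                    "levels": list(self.levels[j]),
                    "probs": self.category_probs[j].tolist(),
                }
                for j, name in enumerate(self.categorical_names)
            },
        }


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------


def split_encoded(X) -> tuple[np.ndarray, np.ndarray, list[str], list[str], list[tuple[str, ...]]]:
    """Split an encoded frame into continuous values and categorical codes.

    Accepts a DataFrame whose categorical columns carry a CategoricalDtype
    (the output of :func:`psaphen.encode.encode_features`) or a plain
    numeric array (treated as all-continuous).
    """
    if isinstance(X, np.ndarray):
        Xc = np.asarray(X, dtype=float)
        if Xc.ndim != 2:
            raise ValueError("expected a 2-D array")
        names = [f"x{j}" for j in range(Xc.shape[1])]
        return Xc, np.empty((len(Xc), 0), dtype=int), names, [], []

    cont_names, cat_names, levels, cont_cols, cat_cols = [], [], [], [], []
    for name in X.columns:
        col = X[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            codes = np.asarray(col.cat.codes)
            if (codes < 0).any():
                raise ValueError(f"missing/unknown category in column {name!r}")
            cat_names.append(name)
            levels.append(tuple(col.cat.categories))
            cat_cols.append(codes)
        else:
            vals = np.asarray(col, dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in continuous column {name!r}")
            cont_names.append(name)
            cont_cols.append(vals)
    Xc = np.column_stack(cont_cols) if cont_cols else np.empty((len(X), 0))
    Xd = np.column_stack(cat_cols) if cat_cols else np.empty((len(X), 0), dtype=int)
    return Xc, Xd, cont_names, cat_names, levels


# ---------------------------------------------------------------------------
# EM primitives (array core)
# ---------------------------------------------------------------------------


def _log_joint(Xc: np.ndarray, Xd: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(n, K) matrix of log(pi_k) + log f_k(y_i)."""
    n = max(len(Xc), len(Xd))
    with np.errstate(divide="ignore"):
        log_joint = np.broadcast_to(np.log(params.weights), (n, params.n_components)).copy()
    if Xc.shape[1]:
        diff = Xc[:, None, :] - params.means[None, :, :]
        log_joint += -0.5 * (
            _LOG2PI + np.log(params.variances)[None] + diff**2 / params.variances[None]
        ).sum(axis=2)
    for j, probs in enumerate(params.category_probs):
        with np.errstate(divide="ignore"):
            log_joint += np.log(probs)[:, Xd[:, j]].T
    return log_joint


def _e_step_arrays(Xc, Xd, params: MixtureParams) -> tuple[np.ndarray, float]:
    log_joint = _log_joint(Xc, Xd, params)
    row_ll = logsumexp(log_joint, axis=1)
    bad = ~np.isfinite(row_ll)
    if bad.any():
        raise FloatingPointError(
            f"all component densities underflowed for row(s) {np.flatnonzero(bad)[:5].tolist()}"
        )
    resp = np.exp(log_joint - row_ll[:, None])
    return resp, float(row_ll.sum())


def _m_step_arrays(
    Xc, Xd, resp, levels_count, variance_floor, alpha
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
    n = resp.shape[0]
    Nk = resp.sum(axis=0)
    weights = Nk / n
    Nk_safe = np.maximum(Nk, np.finfo(float).tiny)
    if Xc.shape[1]:
        means = resp.T @ Xc / Nk_safe[:, None]
        second = resp.T @ (Xc**2) / Nk_safe[:, None]
        variances = np.maximum(second - means**2, variance_floor[None, :])
    else:
        means = np.empty((resp.shape[1], 0))
        variances = np.empty((resp.shape[1], 0))
    category_probs = []
    for j, L in enumerate(levels_count):
        onehot = np.eye(L)[Xd[:, j]]                      # (n, L)
        counts = resp.T @ onehot + alpha                  # (K, L)
        category_probs.append(counts / counts.sum(axis=1, keepdims=True))
    return weights, means, variances, category_probs


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class MixedMixture(ClusterMixin, BaseEstimator):
    """EM-fitted finite mixture over mixed continuous/categorical features.

    Parameters
    ----------
    n_components : int
        Number of latent phenotypes K.
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        EM iteration cap per restart.
    n_restarts : int
        Independent initialisations; the restart with the best final
        log-likelihood wins.
    alpha : float
        Laplace smoothing added to categorical level counts in the M step
        (0 disables smoothing; then the K=1 fit equals sample frequencies).
    variance_floor_frac : float
        Variance floor as a fraction of each feature's pooled variance.
    random_state : int or None
        Seed for initialisation streams.

    Attributes
    ----------
    params_ : MixtureParams
    weights_, means_, variances_, category_probs_ : fitted parameters
    responsibilities_ : (n, K) posterior membership on the training data
    labels_ : hard assignment (argmax responsibility, ties to lower index)
    loglik_, loglik_trace_, n_iter_, converged_, n_free_params_, bic_
    """

    def __init__(
        self,
        n_components: int = 5,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_restarts: int = 10,
        alpha: float = 0.5,
        variance_floor_frac: float = 1e-4,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.alpha = alpha
        self.variance_floor_frac = variance_floor_frac
        self.random_state = random_state

    # -- initialisation ---------------------------------------------------

    @staticmethod
    def _init_matrix(Xc: np.ndarray, Xd: np.ndarray, levels_count: list[int]) -> np.ndarray:
        """Numeric matrix for k-means seeding: z-scored continuous columns
        plus one-hot categorical indicators, so discrete structure is
        visible to the initialiser too."""
        parts = []
        if Xc.shape[1]:
            std = Xc.std(axis=0)
            parts.append((Xc - Xc.mean(axis=0)) / np.where(std > 0, std, 1.0))
        for j, L in enumerate(levels_count):
            parts.append(np.eye(L)[Xd[:, j]])
        return np.column_stack(parts) if parts else np.zeros((max(len(Xc), len(Xd)), 1))

    def _init_resp(self, Z: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        K = self.n_components
        km_seed = int(rng.integers(2**31 - 1))
        labels = KMeans(n_clusters=K, n_init=1, random_state=km_seed).fit_predict(Z)
        resp = np.eye(K)[labels]
        # Dirichlet perturbation keeps the start soft so EM can move points
        # off their k-means seed.
        resp = resp + 0.25 * rng.dirichlet(np.ones(K), size=n)
        return resp / resp.sum(axis=1, keepdims=True)

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        Xc, Xd, cont_names, cat_names, levels = split_encoded(X)
        n = max(len(Xc), len(Xd))
        K = self.n_components
        if n < K:
            raise ValueError(f"n={n} rows cannot support K={K} components")
        levels_count = [len(lv) for lv in levels]
        pooled_var = Xc.var(axis=0) if Xc.shape[1] else np.empty(0)
        variance_floor = self.variance_floor_frac * np.maximum(pooled_var, 1e-12)

        rng = np.random.default_rng(self.random_state)
        restart_rngs = rng.spawn(self.n_restarts)
        Z_init = self._init_matrix(Xc, Xd, levels_count)

        best = None
        for r_rng in restart_rngs:
            resp = self._init_resp(Z_init, n, r_rng)
            trace: list[float] = []
            ll_prev = -np.inf
            converged = False
            for _ in range(self.max_iter):
                resp = self._handle_empty(resp, n)
                w, mu, var, cp = _m_step_arrays(
                    Xc, Xd, resp, levels_count, variance_floor, self.alpha
                )
                params = MixtureParams(w, mu, var, cp, cont_names, cat_names, levels)
                resp, ll = _e_step_arrays(Xc, Xd, params)
                trace.append(ll)
                if np.isfinite(ll_prev) and abs(ll - ll_prev) <= self.tol * (abs(ll_prev) + 1e-12):
                    converged = True
                    break
                ll_prev = ll
            if best is None or trace[-1] > best[0]:
                best = (trace[-1], params, resp, trace, converged)

        ll, params, resp, trace, converged = best
        if not converged:
            warnings.warn("no EM restart converged; returning best restart", stacklevel=2)
        self.params_ = params
        self.weights_ = params.weights
        self.means_ = params.means
        self.variances_ = params.variances
        self.category_probs_ = params.category_probs
        self.responsibilities_ = resp
        self.labels_ = resp.argmax(axis=1)
        self.loglik_ = ll
        self.loglik_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.converged_ = converged
        self.n_free_params_ = params.n_free_params
        self.n_samples_ = n
        self.bic_ = bic_score(ll, params.n_free_params, n)
        return self

    def _handle_empty(self, resp: np.ndarray, n: int) -> np.ndarray:
        """Reseed any near-empty component at the worst-explained point."""
        Nk = resp.sum(axis=0)
        for k in np.flatnonzero(Nk < 1e-6 * n):
            worst = int(resp.max(axis=1).argmin())
            resp[worst] = 0.0
            resp[worst, k] = 1.0
        return resp

    # -- inference --------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        Xc, Xd, *_ = split_encoded(X)
        resp, _ = _e_step_arrays(Xc, Xd, self.params_)
        return resp

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        Xc, Xd, *_ = split_encoded(X)
        _, ll = _e_step_arrays(Xc, Xd, self.params_)
        return ll / max(len(Xc), len(Xd))

    def bic(self, X=None) -> float:
        if X is None:
            return self.bic_
        Xc, Xd, *_ = split_encoded(X)
        _, ll = _e_step_arrays(Xc, Xd, self.params_)
        return bic_score(ll, self.n_free_params_, max(len(Xc), len(Xd)))


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def e_step(X, params: MixtureParams) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and total log-likelihood under ``params``."""
    params.validate()
    Xc, Xd, *_ = split_encoded(X)
    return _e_step_arrays(Xc, Xd, params)


def m_step(X, responsibilities: np.ndarray, alpha: float = 0.5,
           variance_floor_frac: float = 1e-4) -> MixtureParams:
    """Maximisation step: weighted moments and smoothed level frequencies."""
    resp = np.asarray(responsibilities, dtype=float)
    if np.any(np.abs(resp.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("responsibility rows must sum to 1")
    Xc, Xd, cont_names, cat_names, levels = split_encoded(X)
    pooled_var = Xc.var(axis=0) if Xc.shape[1] else np.empty(0)
    floor = variance_floor_frac * np.maximum(pooled_var, 1e-12)
    w, mu, var, cp = _m_step_arrays(Xc, Xd, resp, [len(lv) for lv in levels], floor, alpha)
    return MixtureParams(w, mu, var, cp, cont_names, cat_names, levels)


def bic_score(loglik: float, n_free_params: int, n: int) -> float:
    """BIC = -2 log L + p log n (lower is better)."""
    if n <= 1:
        raise ValueError("BIC requires n > 1")
    return -2.0 * loglik + n_free_params * np.log(n)


def assign_clusters(fit: MixedMixture) -> np.ndarray:
    """Hard labels: argmax responsibility, ties broken to the lower index."""
    return fit.responsibilities_.argmax(axis=1)


@dataclass
class KSelectionTable:
    """BIC grid-search audit trail for the choice of K."""

    grid: list[int]
    bic_by_k: dict[int, float]
    selected_k: int
    decreases: dict[int, float]          # K -> BIC(K) - BIC(K+1)
    gain_ratios: dict[int, float]        # decrease relative to the first decrease
    no_elbow: bool = False
    fits: dict[int, MixedMixture] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.grid,
                "bic": [self.bic_by_k[k] for k in self.grid],
                "decrease_to_next": [self.decreases.get(k, np.nan) for k in self.grid],
                "gain_ratio": [self.gain_ratios.get(k, np.nan) for k in self.grid],
                "selected": [k == self.selected_k for k in self.grid],
            }
        )


def select_k(
    X,
    grid=range(2, 11),
    elbow_ratio: float = 0.10,
    seed: int | None = None,
    n_restarts: int = 10,
    store_fits: bool = False,
    **em_kwargs,
) -> KSelectionTable:
    """Fit every K on the grid and pick the elbow of the BIC curve.

    The elbow is the smallest K from which every remaining BIC decrease on
    the grid falls below ``elbow_ratio`` times the first decrease — i.e.
    the decrease of BIC is minimal for all larger K, not merely for the
    next step, which makes the rule robust to a single under-optimised
    fit.  If the global BIC minimiser is interior to the grid and smaller
    than that elbow, it wins.  If BIC never decreases from the first step
    there is no structure to exploit and the grid minimum is returned with
    ``no_elbow`` set.
    """
    grid = sorted(grid)
    if len(grid) < 2:
        raise ValueError("grid needs at least two K values")
    rng = np.random.default_rng(seed)
    k_seeds = rng.integers(2**31 - 1, size=len(grid))

    fits: dict[int, MixedMixture] = {}
    bic_by_k: dict[int, float] = {}
    for k, s in zip(grid, k_seeds):
        fit = MixedMixture(
            n_components=k, n_restarts=n_restarts, random_state=int(s), **em_kwargs
        ).fit(X)
        fits[k] = fit
        bic_by_k[k] = fit.bic_

    decreases = {k: bic_by_k[k] - bic_by_k[k2] for k, k2 in zip(grid[:-1], grid[1:])}
    first = decreases[grid[0]]
    no_elbow = first <= 0
    ratios = {k: (d / first if first > 0 else np.nan) for k, d in decreases.items()}

    if no_elbow:
        selected = grid[0]
    else:
        selected = None
        for i, k in enumerate(grid[:-1]):
            if all(decreases[k2] < elbow_ratio * first for k2 in grid[i:-1]):
                selected = k
                break
        global_min = min(bic_by_k, key=bic_by_k.get)
        if selected is None:
            selected = global_min
        elif global_min not in (grid[0], grid[-1]) and global_min < selected:
            selected = global_min

    return KSelectionTable(
        grid=list(grid),
        bic_by_k=bic_by_k,
        selected_k=selected,
        decreases=decreases,
        gain_ratios=ratios,
        no_elbow=no_elbow,
        fits=fits if store_fits else None,
    )
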