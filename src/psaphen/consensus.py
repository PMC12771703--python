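"""Consensus-clustering stability assessment by repeated subsampling.

For T iterations a fraction ``a`` of patients is drawn (without
replacement by default), the K-component mixture is refitted on the
subsample, and two indicator matrices are accumulated: I_t, whether a
pair was co-sampled, and M_t, whether a co-sampled pair landed in the
same cluster.  The consensus matrix is the elementwise ratio

    C(i, j) = sum_t M_t(i, j) / sum_t I_t(i, j),

the fraction of times two patients clustered together among the runs that
saw both.  Entries whose pair was never co-sampled are undefined (NaN),
not zero.  A stable clustering shows near-1 consensus within clusters and
near-0 between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mixture import MixedMixture


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering fractions with their co-sampling counts."""

    C: np.ndarray                 # (n, n) float, NaN where never co-sampled
    cosample_counts: np.ndarray   # (n, n) int, sum_t I_t
    n_iterations: int             # requested T
    n_effective: int              # iterations that produced a clustering
    sample_fraction: float

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclass
class StabilityReport:
    """Within/between-cluster consensus summary and a display ordering."""

    within_cluster_mean: dict[int, float]   # NaN where undefined (singleton)
    between_cluster_mean: float
    patient_order: np.ndarray               # permutation of 0..n-1


class ConsensusClustering(BaseEstimator):
    """Monti-style consensus matrix for a K-component mixture clustering.

    Parameters
    ----------
    n_components : int
        K used for every subsample refit.
    n_iterations : int
        Number of subsampling rounds T.
    sample_fraction : float
        Fraction ``a`` of patients drawn each round; must lie in (0, 1].
    with_replacement : bool
        Draw subsamples with replacement instead of without.  Off by
        default: duplicated rows would break the pair-indicator logic.
    n_restarts : int
        EM restarts per subsample refit (kept small for tractability).
    random_state : int or None
        Master seed; per-iteration seeds are derived from it.

    Attributes
    ----------
    consensus_ : ConsensusMatrix
    consensus_matrix_ : alias for ``consensus_.C``
    """

    def __init__(
        self,
        n_components: int = 5,
        n_iterations: int = 200,
        sample_fraction: float = 0.80,
        with_replacement: bool = False,
        n_restarts: int = 3,
        max_iter: int = 300,
        tol: float = 1e-5,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_iterations = n_iterations
        self.sample_fraction = sample_fraction
        self.with_replacement = with_replacement
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        a = self.sample_fraction
        if not 0.0 < a <= 1.0:
            raise ValueError(f"sample_fraction must be in (0, 1], got {a}")
        n = len(X)
        m = int(np.floor(a * n))
        if m < self.n_components:
            raise ValueError(f"subsample size {m} cannot support K={self.n_components}")

        rng = np.random.default_rng(self.random_state)
        iter_seeds = rng.integers(2**31 - 1, size=2 * self.n_iterations).reshape(-1, 2)

        M = np.zeros((n, n))
        I = np.zeros((n, n), dtype=int)
        n_effective = 0
        for t in range(self.n_iterations):
            draw_seed, fit_seed = iter_seeds[t]
            draw_rng = np.random.default_rng(int(draw_seed))
            if self.with_replacement:
                idx = np.unique(draw_rng.integers(n, size=m))
            else:
                idx = draw_rng.choice(n, size=m, replace=False)
            sub = X.iloc[idx] if isinstance(X, pd.DataFrame) else X[idx]

            labels = self._fit_subsample(sub, int(fit_seed))
            if labels is None:
                warnings.warn(f"consensus iteration {t} failed to converge; skipped",
                              stacklevel=2)
                continue
            n_effective += 1
            block = np.ix_(idx, idx)
            I[block] += 1
            M[block] += labels[:, None] == labels[None, :]

        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(I > 0, M / np.maximum(I, 1), np.nan)
        self.consensus_ = ConsensusMatrix(
            C=C,
            cosample_counts=I,
            n_iterations=self.n_iterations,
            n_effective=n_effective,
            sample_fraction=a,
        )
        self.consensus_matrix_ = C
        return self

    def _fit_subsample(self, sub, seed: int):
        """Fit on one subsample; retry once on non-convergence, else skip."""
        for attempt in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedMixture(
                    n_components=self.n_components,
                    n_restarts=self.n_restarts,
                    max_iter=self.max_iter,
                    tol=self.tol,
                    random_state=seed + attempt,
                ).fit(sub)
            if fit.converged_:
                return fit.labels_
        return None


def consensus_matrix(
    X,
    n_components: int,
    n_iterations: int = 200,
    sample_fraction: float = 0.80,
    seed: int | None = None,
    **kwargs,
) -> ConsensusMatrix:
    """Functional one-shot form of :class:`ConsensusClustering`."""
    est = ConsensusClustering(
        n_components=n_components,
        n_iterations=n_iterations,
        sample_fraction=sample_fraction,
        random_state=seed,
        **kwargs,
    ).fit(X)
    return est.consensus_


def stability_summary(cons: ConsensusMatrix, labels) -> StabilityReport:
    """Mean within- and between-cluster consensus plus a display ordering.

    Undefined (never co-sampled) entries are excluded from every average.
    Size-1 clusters have no within pair, hence an undefined (NaN) mean.
    Patients are ordered by cluster, then by descending mean consensus with
    their own cluster, which is the ordering used for consensus heatmaps.
    """
    labels = np.asarray(labels)
    C = cons.C
    n = cons.n
    if len(labels) != n:
        raise ValueError("labels must cover every patient in the consensus matrix")

    iu, ju = np.triu_indices(n, k=1)
    defined = ~np.isnan(C[iu, ju])
    same = labels[iu] == labels[ju]

    within: dict[int, float] = {}
    for k in np.unique(labels):
        mask = defined & same & (labels[iu] == k)
        within[int(k)] = float(C[iu[mask], ju[mask]].mean()) if mask.any() else float("nan")
    between_mask = defined & ~same
    between = float(C[iu[between_mask], ju[between_mask]].mean()) if between_mask.any() else float("nan")

    # mean consensus with own cluster, per patient
    own = np.full(n, np.nan)
    for i in range(n):
        peers = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        vals = C[i, peers]
        vals = vals[~np.isnan(vals)]
        own[i] = vals.mean() if vals.size else -np.inf
    order = np.lexsort((-own, labels))

    return StabilityReport(
        within_cluster_mean=within, between_cluster_mean=between, patient_order=order
    )
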