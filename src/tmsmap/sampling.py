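"""Subset selection of coil configurations.

Farthest point sampling (FPS) greedily picks, at each step, the candidate
|E| map whose minimum Euclidean distance to the already-selected maps is
largest:

    s_n = argmax_{E_c in C \\ S}  min_{E_j in S} ||E_c - E_j||

The first sample is drawn uniformly at random (or forced).  Random
sampling — the baseline protocol — draws uniformly without replacement.
Both are exposed as sklearn-style estimators plus thin functional wrappers.

Determinism contract: ties in the argmax (and the inner min) are broken by
the smallest candidate index; all randomness comes from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .efield import CandidateSet


@dataclass
class SampleSelection:
    """Ordered selection of candidate indices with its min-distance trace.

    ``min_dist_trace[i]`` is the minimum distance of the i-th selected map to
    the maps selected before it (first entry is the ``inf`` sentinel).  For
    FPS the trace is non-increasing from step 2 onward.
    """

    order: np.ndarray
    method: str
    seed: int | None = None
    min_dist_trace: np.ndarray | None = None

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=np.int64)
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.order)


def _as_matrix(candidates) -> np.ndarray:
    if isinstance(candidates, CandidateSet):
        return candidates.maps
    X = np.asarray(candidates, dtype=float)
    if X.ndim != 2:
        raise ValueError("candidates must be a (Nc, K) matrix")
    return X


def _row_distances(X: np.ndarray, row: np.ndarray) -> np.ndarray:
    # kept in one place so incremental FPS and the oracle share the exact
    # floating-point reduction (required for bitwise equivalence)
    diff = X - row
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def _check_n_samples(n_samples: int, n_candidates: int) -> None:
    if n_candidates < 1:
        raise ValueError("empty candidate set")
    if not 1 <= n_samples <= n_candidates:
        raise ValueError(
            f"n_samples must be in [1, {n_candidates}], got {n_samples}"
        )


class FarthestPointSampler(BaseEstimator):
    """Greedy max-min selection of ``n_samples`` rows of X.

    Parameters
    ----------
    n_samples : number of rows to select (1 ≤ n_samples ≤ Nc).
    first_index : force the first selected row; if None, drawn uniformly
        from ``random_state``.
    random_state : seed for the first-sample draw.

    Attributes (after ``fit``)
    --------------------------
    indices_ : selection order.
    min_dist_trace_ : per-step min distance to the previously selected rows.
    """

    def __init__(self, n_samples: int = 10, first_index: int | None = None,
                 random_state: int | None = None):
        self.n_samples = n_samples
        self.first_index = first_index
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        nc = X.shape[0]
        _check_n_samples(self.n_samples, nc)
        if self.first_index is not None:
            first = int(self.first_index)
            if not 0 <= first < nc:
                raise ValueError("first_index out of range")
        else:
            first = int(np.random.default_rng(self.random_state).integers(nc))

        order = np.empty(self.n_samples, dtype=np.int64)
        trace = np.full(self.n_samples, np.inf)
        min_dist = np.full(nc, np.inf)
        cur = first
        for step in range(self.n_samples):
            order[step] = cur
            if step > 0:
                trace[step] = min_dist[cur]
            min_dist[cur] = -np.inf  # exclude selected rows from the argmax
            if step + 1 == self.n_samples:
                break
            d = _row_distances(X, X[cur])
            np.minimum(min_dist, d, out=min_dist)
            # np.argmax returns the first maximizer -> smallest-index tie-break
            cur = int(np.argmax(min_dist))
        self.indices_ = order
        self.min_dist_trace_ = trace
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        return X[self.indices_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class RandomSampler(BaseEstimator):
    """Uniform selection of ``n_samples`` rows without replacement."""

    def __init__(self, n_samples: int = 10, random_state: int | None = None):
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        _check_n_samples(self.n_samples, X.shape[0])
        rng = np.random.default_rng(self.random_state)
        self.indices_ = rng.choice(
            X.shape[0], size=self.n_samples, replace=False
        ).astype(np.int64)
        self.min_dist_trace_ = selection_trace(X, self.indices_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        return X[self.indices_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def selection_trace(X, order: np.ndarray) -> np.ndarray:
    """Min distance of each selected row to the rows selected before it."""
    X = _as_matrix(X)
    order = np.asarray(order, dtype=np.int64)
    trace = np.full(len(order), np.inf)
    for i in range(1, len(order)):
        d = _row_distances(X[order[:i]], X[order[i]])
        trace[i] = d.min()
    return trace


def fps_sample(
    candidates,
    n_samples: int,
    seed: int | None = None,
    first_index: int | None = None,
) -> SampleSelection:
    """Farthest point sampling of ``n_samples`` candidate |E| maps."""
    est = FarthestPointSampler(
        n_samples=n_samples, first_index=first_index, random_state=seed
    ).fit(candidates)
    return SampleSelection(
        order=est.indices_, method="fps", seed=seed,
        min_dist_trace=est.min_dist_trace_,
    )


def random_sample(candidates, n_samples: int, seed: int | None = None) -> SampleSelection:
    """Uniform random selection without replacement (baseline protocol)."""
    est = RandomSampler(n_samples=n_samples, random_state=seed).fit(candidates)
    return SampleSelection(
        order=est.indices_, method="random", seed=seed,
        min_dist_trace=est.min_dist_trace_,
    )


def fps_bruteforce_oracle(
    candidates, n_samples: int, first_index: int
) -> SampleSelection:
    """Reference FPS that re-evaluates the max-min criterion from scratch at
    every step, with no incremental caching.  Same tie-break rule as
    :class:`FarthestPointSampler`; intended for verification at small Nc."""
    X = _as_matrix(candidates)
    nc = X.shape[0]
    _check_n_samples(n_samples, nc)
    if not 0 <= first_index < nc:
        raise ValueError("first_index out of range")
    selected = [int(first_index)]
    trace = [np.inf]
    while len(selected) < n_samples:
        best_idx, best_val = -1, -np.inf
        for c in range(nc):
            if c in selected:
                continue
            dmin = np.inf
            for j in selected:
                d = _row_distances(X[c : c + 1], X[j])[0]
                if d < dmin:
                    dmin = d
            if dmin > best_val:  # strict: first (smallest) index wins ties
                best_val, best_idx = dmin, c
        selected.append(best_idx)
        trace.append(best_val)
    return SampleSelection(
        order=np.array(selected), method="fps", seed=None,
        min_dist_trace=np.array(trace),
    )


def selection_frame(selection: SampleSelection, candidates: CandidateSet):
    """Tidy per-step table (step, candidate_index, x, y, alpha, min_dist)."""
    import pandas as pd

    cfg = candidates.config_frame().iloc[selection.order].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "step": np.arange(len(selection)),
            "candidate_index": selection.order,
            "x": cfg["x"],
            "y": cfg["y"],
            "alpha": cfg["alpha"],
            "min_dist": selection.min_dist_trace,
        }
    )
    return out
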