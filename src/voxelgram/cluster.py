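"""Multichannel fuzzy c-means clustering of 2D or 3D elemental images.

Every in-mask pixel/voxel becomes one row of a feature matrix with one
column per channel, min-max normalised to [0, 1] so that channels of
wildly different dynamic range (e.g. P in tens of thousands of CPS versus
Co in fractions of a ug/g) contribute comparably to the Euclidean
distance.  Fuzzy c-means (Bezdek) then iterates the two coupled updates

    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))        (memberships)
    v_k  = sum_i u_ik^m x_i / sum_i u_ik^m          (centres)

until the maximum relative centre change drops below ``tol`` or the
iteration cap is reached.  The fuzzifier m (> 1, default 2) controls how
soft the memberships are; m -> 1 approaches hard k-means.  Clusters are
re-ordered by their first-feature centre value so that results are
deterministic and comparable across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FeatureMatrix",
    "FCMConfig",
    "FCMResult",
    "flatten",
    "fcm",
    "cluster_report",
    "label_map",
]


@dataclass
class FeatureMatrix:
    """n x d feature matrix of in-mask elements plus coordinate bookkeeping.

    ``coords`` maps row i to its source coordinate tuple ((y, x) or
    (z, y, x)); ``norms`` records the per-channel (min, max) used for the
    min-max normalisation so reports can be expressed in original units.
    """

    X: np.ndarray
    channels: tuple[str, ...]
    coords: np.ndarray
    norms: np.ndarray  # (d, 2): min, max per channel in original units
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.X.shape[0] != self.coords.shape[0]:
            raise ValueError("one coordinate per row required")

    def denormalise(self, values: np.ndarray) -> np.ndarray:
        """Map normalised [0, 1] values back to original units."""
        lo, hi = self.norms[:, 0], self.norms[:, 1]
        return values * (hi - lo) + lo


@dataclass(frozen=True)
class FCMConfig:
    c: int = 5
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    variant: str = "bezdek"  # or "inverse_distance"
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("cluster count c must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.variant not in ("bezdek", "inverse_distance"):
            raise ValueError("variant must be 'bezdek' or 'inverse_distance'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class FCMResult:
    centres: np.ndarray           # (c, d), normalised feature space
    memberships: np.ndarray       # (n, c), rows sum to 1
    labels: np.ndarray            # (n,), argmax membership, ties -> lowest
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def flatten(data: np.ndarray | Sequence[np.ndarray],
            mask: np.ndarray | None = None,
            channels: Sequence[str] | None = None,
            norm: str = "minmax") -> FeatureMatrix:
    """Convert a (channel, ...) stack or list of channel arrays into a
    normalised feature matrix over in-mask elements.

    ``norm`` is ``"minmax"`` (default, maps each channel to [0, 1] and
    records the anchors for de-normalisation) or ``"zscore"``.  Channels
    with zero dynamic range carry no clustering information and are
    dropped.
    """
    if isinstance(data, (list, tuple)):
        arr = np.stack([np.asarray(a, dtype=float) for a in data])
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim < 3:
            arr = arr[None]
    d = arr.shape[0]
    spatial_shape = arr.shape[1:]
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(d))
    channels = tuple(channels)
    if len(channels) != d:
        raise ValueError("one label per channel required")
    if mask is None:
        mask = np.ones(spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial_shape:
        raise ValueError("mask shape must match the channel arrays")
    if not mask.any():
        raise ValueError("empty mask: nothing to cluster")

    if norm not in ("minmax", "zscore"):
        raise ValueError("norm must be 'minmax' or 'zscore'")
    coords = np.argwhere(mask)
    raw = np.stack([arr[i][mask] for i in range(d)], axis=1)
    keep, norms, cols = [], [], []
    for i, ch in enumerate(channels):
        lo, hi = float(raw[:, i].min()), float(raw[:, i].max())
        if hi <= lo:
            continue  # constant channel: degenerate normalisation, drop
        keep.append(ch)
        if norm == "minmax":
            norms.append((lo, hi))
            cols.append((raw[:, i] - lo) / (hi - lo))
        else:
            mu, sd = float(raw[:, i].mean()), float(raw[:, i].std())
            # recorded so denormalise(v) = v*(hi-lo)+lo maps back exactly
            norms.append((mu, mu + sd))
            cols.append((raw[:, i] - mu) / sd)
    if not cols:
        raise ValueError("all channels are constant; nothing to cluster")
    return FeatureMatrix(X=np.stack(cols, axis=1), channels=tuple(keep),
                         coords=coords, norms=np.asarray(norms),
                         shape=spatial_shape)


def _memberships(d2: np.ndarray, m: float, variant: str) -> np.ndarray:
    """Membership matrix from squared distances, handling coincidences."""
    n, c = d2.shape
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    if variant == "bezdek":
        power = -1.0 / (m - 1.0)
        with np.errstate(divide="ignore"):
            w = np.where(zero, np.inf, d2) ** power
    else:  # plain normalised inverse distance
        with np.errstate(divide="ignore"):
            w = 1.0 / np.sqrt(np.where(zero, np.inf, d2))
    with np.errstate(invalid="ignore"):
        u = w / w.sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = 0.0
        first_zero = np.argmax(zero[any_zero], axis=1)
        u[np.nonzero(any_zero)[0], first_zero] = 1.0
    return u


def fcm(matrix: FeatureMatrix, config: FCMConfig) -> FCMResult:
    """Run fuzzy c-means on a feature matrix.

    Initial centres are drawn uniformly (without replacement) from the
    data points using the configured seed; a data point coincident with a
    centre receives full membership to that centre.  The objective
    J = sum_ik u_ik^m d_ik^2 is recorded each iteration and is
    non-increasing.  On return, clusters are sorted by their first-feature
    centre value, memberships permuted accordingly, and hard labels taken
    as the argmax membership (ties break to the lowest cluster index).
    With ``n_restarts`` > 1, independent runs from spawned seeds are
    performed and the result with the lowest final objective kept.
    """
    if config.n_restarts > 1:
        from dataclasses import replace as dc_replace

        seeds = np.random.SeedSequence(config.seed).generate_state(
            config.n_restarts) % (2 ** 31)
        runs = [fcm(matrix, dc_replace(config, seed=int(s), n_restarts=1))
                for s in seeds]
        return min(runs, key=lambda r: r.objective[-1] if r.objective
                   else np.inf)
    X = matrix.X
    n, d = X.shape
    c, m = config.c, config.m
    if n < c:
        raise ValueError(f"need at least c={c} data points, got {n}")
    rng = np.random.default_rng(config.seed)
    centres = X[rng.choice(n, size=c, replace=False)].copy()

    objective: list[float] = []
    converged = False
    n_iter = 0
    u = _memberships(cdist(X, centres, "sqeuclidean"), m, config.variant)
    for n_iter in range(1, config.max_iter + 1):
        um = u ** m
        denom = um.sum(axis=0)
        # an empty cluster keeps its previous centre
        new_centres = np.where(denom[:, None] > 0,
                               (um.T @ X) / np.maximum(denom[:, None], 1e-300),
                               centres)
        delta = np.max(np.abs(new_centres - centres)
                       / np.maximum(np.abs(centres), 1e-12))
        centres = new_centres
        d2 = cdist(X, centres, "sqeuclidean")
        u = _memberships(d2, m, config.variant)
        objective.append(float(np.sum((u ** m) * d2)))
        if delta < config.tol:
            converged = True
            break

    order = np.argsort(centres[:, 0], kind="stable")
    centres = centres[order]
    u = u[:, order]
    labels = np.argmax(u, axis=1)  # np.argmax ties -> lowest index
    return FCMResult(centres=centres, memberships=u, labels=labels,
                     objective=objective, n_iter=n_iter, converged=converged)


def cluster_report(result: FCMResult, matrix: FeatureMatrix) -> list[dict]:
    """Per-cluster composition: for every cluster and channel, the
    membership-weighted mean (in original units), the min/max over
    hard-assigned members, the member count and the percentage of the
    dataset.  Empty clusters report count 0 with stats absent."""
    if result.memberships.shape[0] != matrix.X.shape[0]:
        raise ValueError("result and matrix row counts differ")
    n = matrix.X.shape[0]
    X_orig = matrix.denormalise(matrix.X)
    rows: list[dict] = []
    for k in range(result.centres.shape[0]):
        members = result.labels == k
        count = int(members.sum())
        w = result.memberships[:, k]
        wsum = w.sum()
        entry: dict = {
            "cluster": k + 1,
            "count": count,
            "percent": 100.0 * count / n,
            "channels": {},
        }
        for j, ch in enumerate(matrix.channels):
            stats: dict = {
                "mean": float((w @ X_orig[:, j]) / wsum) if wsum > 0 else None,
            }
            if count > 0:
                stats["min"] = float(X_orig[members, j].min())
                stats["max"] = float(X_orig[members, j].max())
            entry["channels"][ch] = stats
        rows.append(entry)
    return rows


def report_to_frame(report: list[dict]):
    """Flatten a cluster report to a pandas DataFrame (one row per
    cluster x channel) for CSV export."""
    import pandas as pd

    recs = []
    for entry in report:
        for ch, stats in entry["channels"].items():
            recs.append({"cluster": entry["cluster"], "channel": ch,
                         "mean": stats.get("mean"), "min": stats.get("min"),
                         "max": stats.get("max"), "count": entry["count"],
                         "percent": entry["percent"]})
    return pd.DataFrame.from_records(recs)


def label_map(result: FCMResult, matrix: FeatureMatrix,
              shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Paint hard cluster labels back into image/volume space.

    In-mask elements carry 1-based cluster labels; everything else is 0.
    """
    shape = shape or matrix.shape
    out = np.zeros(shape, dtype=np.int32)
    idx = tuple(matrix.coords[:, i] for i in range(matrix.coords.shape[1]))
    out[idx] = result.labels + 1
    return out
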