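"""Molting-cycle expression preprocessing, fuzzy c-means, pre-molt selection.

The screening idea: genes driving the molting cycle peak shortly before each
ecdysis. After replicate averaging, merging of split gene models, and a
3-point overlapping-window smoothing that damps developmental jitter, genes
are soft-clustered by fuzzy c-means on z-scored profiles, and the clusters
whose centers repeatedly peak in a window just before the molts supply the
candidate regulator set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import ExpressionTimecourse, FormatError


class ConfigurationError(ValueError):
    pass


# -- preprocessing --------------------------------------------------------


def collapse_replicates_and_merge(
    tc: ExpressionTimecourse,
    merge_groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> ExpressionTimecourse:
    """Average replicate columns per stage and sum split gene models.

    Replicates (columns sharing a ``replicate_group``) collapse to their
    arithmetic mean at that stage's time. Each entry of ``merge_groups``
    replaces the listed gene models by their per-time-point sum under the
    new ID (for genes whose model was split in the annotation).
    """
    values, times = tc.values, tc.times
    if tc.replicate_groups is not None:
        groups = list(dict.fromkeys(tc.replicate_groups))  # stable order
        cols, new_times = [], []
        rep = np.asarray(tc.replicate_groups)
        for g in groups:
            idx = np.where(rep == g)[0]
            cols.append(values.iloc[:, idx].mean(axis=1))
            new_times.append(float(np.mean(times[idx])))
        values = pd.concat(cols, axis=1)
        values.columns = [f"t{t:g}" for t in new_times]
        times = np.array(new_times)
        order = np.argsort(times)
        values = values.iloc[:, order]
        times = times[order]
    if merge_groups:
        values = values.copy()
        for new_id, members in merge_groups.items():
            missing = [m for m in members if m not in values.index]
            if missing:
                raise KeyError(f"merge group {new_id!r}: unknown gene IDs {missing}")
            merged = values.loc[list(members)].sum(axis=0)
            values = values.drop(index=list(members))
            values.loc[new_id] = merged
    return ExpressionTimecourse(values, times, tc.molt_times, None, tc.unit)


def smooth_windows(tc: ExpressionTimecourse, w: int = 3) -> ExpressionTimecourse:
    """Overlapping-window mean: output point i carries the mean of the w
    points centred on i; endpoints are dropped (length shrinks by w - 1)."""
    if w % 2 != 1 or w < 3:
        raise ConfigurationError("window size must be odd and >= 3")
    if tc.replicate_groups is not None:
        raise ConfigurationError("collapse replicates before smoothing")
    n = tc.values.shape[1]
    if n < w:
        raise FormatError(f"need at least {w} time points, have {n}")
    half = w // 2
    arr = tc.values.to_numpy(dtype=float)
    kernel = np.ones(w) / w
    sm = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, arr)
    times = tc.times[half : n - half]
    out = pd.DataFrame(sm, index=tc.values.index, columns=[f"t{t:g}" for t in times])
    molt = tc.molt_times[(tc.molt_times >= times.min()) & (tc.molt_times <= times.max())]
    return ExpressionTimecourse(out, times, molt, None, tc.unit)


# -- fuzzy c-means --------------------------------------------------------


@dataclass
class FcmResult:
    membership: np.ndarray  # genes x clusters, rows sum to 1
    centers: np.ndarray  # clusters x features
    m: float
    objective: float
    objective_history: List[float]
    n_iter: int
    seed: int

    def hard_labels(self) -> np.ndarray:
        return self.membership.argmax(axis=1)


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ik = ( sum_j (d_ik/d_jk)^(2/(m-1)) )^-1, with the zero-distance
    convention: a point coincident with a center gets membership 1 there."""
    n, c = d2.shape
    u = np.zeros((n, c))
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    if any_zero.any():
        rows = np.where(any_zero)[0]
        for i in rows:
            hits = np.where(zero[i])[0]
            u[i, hits[0]] = 1.0
    ok = ~any_zero
    if ok.any():
        p = 1.0 / (m - 1.0)
        inv = d2[ok] ** -p  # (d^2)^(1/(m-1)) = d^(2/(m-1))
        u[ok] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> FcmResult:
    """Standard fuzzy c-means by alternating optimization.

    Minimizes J = sum_ik u_ik^m ||x_i - v_k||^2 with memberships
    u_ik = (sum_j (d_ik/d_jk)^(2/(m-1)))^-1 and centers
    v_k = sum_i u_ik^m x_i / sum_i u_ik^m, starting from a random membership
    matrix drawn from ``seed``; stops when the objective improves by less
    than ``tol``. Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")
    n = X.shape[0]
    if c < 2:
        raise ConfigurationError("cluster count must be >= 2")
    if c >= n:
        raise ConfigurationError(f"cluster count {c} must be < n_genes {n}")
    if m <= 1:
        raise ConfigurationError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    history: List[float] = []
    prev = np.inf
    for it in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = cdist(X, centers, "sqeuclidean")
        u = _fcm_memberships(d2, m)
        obj = float((u**m * d2).sum())
        history.append(obj)
        if abs(prev - obj) < tol:
            break
        prev = obj
    return FcmResult(u, centers, m, history[-1], history, len(history), seed)


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Z-score each row (gene); constant rows map to zeros."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def cluster_timecourse(
    tc: ExpressionTimecourse,
    c: int,
    seed: int = 0,
    m: float = 2.0,
    standardize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FcmResult:
    """Fuzzy c-means over a (collapsed, smoothed) timecourse.

    Profiles are z-scored by default so clustering captures shape, not
    absolute abundance; cluster centers are reported on the same scale.
    """
    X = tc.values.to_numpy(dtype=float)
    if standardize:
        X = standardize_rows(X)
    return fuzzy_cmeans(X, c=c, m=m, tol=tol, max_iter=max_iter, seed=seed)


# -- pre-molt cluster selection -------------------------------------------


def _local_max_indices(y: np.ndarray) -> np.ndarray:
    """Indices of strict-ish local maxima (plateaus excluded, endpoints
    compared one-sided)."""
    n = len(y)
    idx = []
    for i in range(n):
        left = y[i] > y[i - 1] if i > 0 else True
        right = y[i] > y[i + 1] if i < n - 1 else True
        left_ge = y[i] >= y[i - 1] if i > 0 else True
        right_ge = y[i] >= y[i + 1] if i < n - 1 else True
        strict_somewhere = (i > 0 and y[i] > y[i - 1]) or (i < n - 1 and y[i] > y[i + 1])
        if left_ge and right_ge and strict_somewhere and (left or right):
            idx.append(i)
    return np.array(idx, dtype=int)


def select_premolt_clusters(
    result: FcmResult,
    tc: ExpressionTimecourse,
    delta: float = 0.25,
    majority: float = 0.5,
    min_peak_z: float = 1.0,
) -> Tuple[List[int], List[str]]:
    """Pick clusters whose (z-scored) center peaks just before the molts.

    A cluster is selected iff its center has a prominent local maximum
    (z-score >= ``min_peak_z``, so near-flat centers whose standardized
    noise wiggles everywhere do not qualify) inside ``(molt - delta *
    preceding intermolt interval, molt]`` for strictly more than
    ``majority`` of the molt events. Returns (selected cluster indices,
    candidate genes = genes whose max-membership cluster is selected).
    """
    molts = tc.molt_times
    if len(molts) == 0:
        raise ConfigurationError("no molt events annotated")
    times = tc.times
    if result.centers.shape[1] != len(times):
        raise ConfigurationError("cluster centers not on the time grid")
    start = times.min()
    selected: List[int] = []
    for k, center in enumerate(result.centers):
        sd = center.std()
        z = (center - center.mean()) / (sd if sd > 0 else 1.0)
        idx = _local_max_indices(z)
        peaks = times[idx[z[idx] >= min_peak_z]] if len(idx) else times[:0]
        hits = 0
        for j, molt in enumerate(molts):
            prev = molts[j - 1] if j > 0 else start
            lo = molt - delta * (molt - prev)
            if ((peaks > lo) & (peaks <= molt)).any():
                hits += 1
        if hits > majority * len(molts):
            selected.append(k)
    labels = result.hard_labels()
    genes = [g for g, lab in zip(tc.genes, labels) if lab in selected]
    return selected, genes
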