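"""Sample clustering and group-indicative CNVRs.

Carrier incidence over CNVRs is summarised as a binary sample x CNVR matrix.
Samples are clustered hierarchically on Jaccard distance between carrier
profiles; group-indicative CNVRs are found by indicator-value analysis
(IndVal): for each CNVR and group g,

    A_g  (specificity) = mean presence in g / sum over groups of mean presence
    B_g  (fidelity)    = fraction of group-g samples carrying the CNVR
    IndVal             = max over g of sqrt(A_g * B_g)

with significance from permutation of the group labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .core import Cnvr

_EPS = 1e-12


def presence_matrix(cnvrs: Sequence[Cnvr], samples: Sequence[str]) -> pd.DataFrame:
    """Binary samples x CNVRs carrier matrix (1 iff the sample carries the CNVR)."""
    known = set(samples)
    mat = pd.DataFrame(0, index=list(samples), columns=[r.id for r in cnvrs], dtype=int)
    for r in cnvrs:
        for s in r.carriers:
            if s not in known:
                raise ValueError(f"CNVR {r.id} carrier {s!r} is not a known sample")
            mat.loc[s, r.id] = 1
    return mat


def jaccard_distances(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed pairwise Jaccard distances between binary carrier profiles.

    Convention for degenerate profiles: two all-zero profiles are at distance
    0; an all-zero profile is at distance 1 from any non-empty one.
    """
    x = matrix.to_numpy(dtype=bool)
    n = x.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            union = np.count_nonzero(x[i] | x[j])
            if union == 0:
                out[k] = 0.0
            else:
                out[k] = 1.0 - np.count_nonzero(x[i] & x[j]) / union
            k += 1
    return out


def cluster_samples(
    matrix: pd.DataFrame,
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical agglomeration of samples on Jaccard distance.

    Returns the SciPy linkage matrix and the row labels in order.  The result
    depends only on the pairwise distances, so it is invariant to CNVR
    (column) order.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two samples to cluster")
    return linkage(jaccard_distances(matrix), method=method), list(matrix.index)


@dataclass(frozen=True)
class IndicatorResult:
    """IndVal outcome for one CNVR: best group, components, statistic and p."""

    cnvr_id: str
    best_group: str
    specificity: float  # A of the best group
    fidelity: float  # B of the best group
    statistic: float  # sqrt(A * B)
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.statistic <= 1.0):
            raise ValueError("IndVal statistic must be in [0, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must be in (0, 1]")


def _indval_components(
    x: np.ndarray, gidx: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group A (specificity) and B (fidelity) matrices, groups x columns.

    ``x``: samples x columns binary array; ``gidx``: group index per sample;
    ``sizes``: samples per group.
    """
    k = sizes.size
    sums = np.zeros((k, x.shape[1]))
    for g in range(k):
        sums[g] = x[gidx == g].sum(axis=0)
    b = sums / sizes[:, None]  # per-group mean presence == fidelity
    denom = b.sum(axis=0)
    a = np.divide(b, denom[None, :], out=np.zeros_like(b), where=denom > 0)
    return a, b


def _indval_stats(x: np.ndarray, gidx: np.ndarray, sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column IndVal statistic (max over groups of sqrt(A*B)) and best group."""
    a, b = _indval_components(x, gidx, sizes)
    stat = np.sqrt(a * b)
    best = stat.argmax(axis=0)
    return stat.max(axis=0), best


def indval(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> list[IndicatorResult]:
    """Indicator-value analysis of every CNVR column against the sample groups.

    ``method="permutation"`` estimates p as (1 + #{permuted statistic >=
    observed}) / (n_perm + 1) over random relabellings; ``method="exact"``
    enumerates every ordering of the label vector (feasible only for small
    sample counts) and reports the exact tail fraction.  An all-zero column
    gets statistic 0 and p = 1.
    """
    missing = [s for s in matrix.index if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    labels = np.array([groups[s] for s in matrix.index])
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    gidx = np.array([names.index(l) for l in labels])
    sizes = np.bincount(gidx, minlength=len(names)).astype(float)
    if (sizes == 0).any():
        raise ValueError("every group must be non-empty")
    x = matrix.to_numpy(dtype=float)
    obs, best = _indval_stats(x, gidx, sizes)

    if method == "exact":
        if x.shape[0] > 9:
            raise ValueError("exact enumeration is limited to <= 9 samples")
        perms = list(itertools.permutations(gidx))
        count = np.zeros_like(obs)
        for perm in perms:
            stat, _ = _indval_stats(x, np.array(perm), sizes)
            count += stat >= obs - _EPS
        pvals = count / len(perms)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = np.zeros_like(obs)
        g = gidx.copy()
        for _ in range(n_perm):
            rng.shuffle(g)
            stat, _ = _indval_stats(x, g, sizes)
            count += stat >= obs - _EPS
        pvals = (1.0 + count) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    a_mat, b_mat = _indval_components(x, gidx, sizes)
    results = []
    for j, cid in enumerate(matrix.columns):
        empty = x[:, j].sum() == 0
        results.append(
            IndicatorResult(
                cnvr_id=str(cid),
                best_group=names[best[j]],
                specificity=float(a_mat[best[j], j]),
                fidelity=float(b_mat[best[j], j]),
                statistic=float(obs[j]),
                p_value=1.0 if empty else float(pvals[j]),
            )
        )
    return results


def significant(results: Sequence[IndicatorResult], alpha: float = 0.05) -> list[IndicatorResult]:
    """Results with permutation p below ``alpha`` (no multiplicity correction)."""
    return [r for r in results if r.p_value < alpha]


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values, offered as an optional multiplicity correction."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj
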