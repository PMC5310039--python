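"""Population differentiation: the K_ST statistic with permutation tests.

K_ST (Hudson, Boos & Kaplan 1992) is an F_ST analogue for sequence
data: K_S is the weighted average of the mean pairwise difference
counts within each population (weights n_j/n), K_T the mean pairwise
difference count over all pooled pairs, and

    K_ST = 1 - K_S / K_T

measures the proportion of pairwise diversity attributable to
between-population differentiation.  Significance comes from a
one-tailed label-permutation test (large K_ST indicates structure);
K_T is invariant under label permutation, so only K_S is recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import SequenceAlignment
from .popgen_stats import pairwise_difference_matrix


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class KstResult:
    k_st: float | None
    k_s: float
    k_t: float
    k_within: Mapping[str, float]
    n_per_pop: Mapping[str, int]
    p: float | None = None
    permutations: int | None = None
    seed: int | None = None
    permutation_mean: float | None = None
    permutation_q95: float | None = None


def _prepare(
    alignment: SequenceAlignment, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if len(labels) != alignment.n:
        raise StructureError("one label per sequence required")
    labels = list(labels)
    pops = sorted(set(labels))
    sizes = {p: labels.count(p) for p in pops}
    small = [p for p in pops if sizes[p] < 2]
    if small:
        warnings.warn(
            f"excluding populations with fewer than 2 sequences: {small}",
            stacklevel=3,
        )
    keep_pops = [p for p in pops if sizes[p] >= 2]
    if len(keep_pops) < 2:
        raise StructureError("need at least 2 populations with >=2 sequences each")
    keep_idx = [i for i, lab in enumerate(labels) if lab in keep_pops]
    sub = alignment.select_samples([alignment.ids[i] for i in keep_idx])
    dist = pairwise_difference_matrix(sub)
    lab_arr = np.array([labels[i] for i in keep_idx])
    return dist, lab_arr, keep_pops


def _k_s(dist: np.ndarray, lab_arr: np.ndarray, pops: list[str]) -> tuple[float, dict, dict]:
    n = len(lab_arr)
    k_within: dict[str, float] = {}
    sizes: dict[str, int] = {}
    k_s = 0.0
    for p in pops:
        mask = lab_arr == p
        nj = int(mask.sum())
        block = dist[np.ix_(mask, mask)]
        kj = block.sum() / (nj * (nj - 1))
        k_within[p] = float(kj)
        sizes[p] = nj
        k_s += (nj / n) * kj
    return k_s, k_within, sizes


def k_st(alignment: SequenceAlignment, labels: Sequence[str]) -> KstResult:
    """Point estimate of K_ST; K_T = 0 (no variation) gives k_st = None."""
    dist, lab_arr, pops = _prepare(alignment, labels)
    n = len(lab_arr)
    k_t = float(dist.sum() / (n * (n - 1)))
    k_s, k_within, sizes = _k_s(dist, lab_arr, pops)
    if k_t == 0.0:
        return KstResult(None, k_s, k_t, k_within, sizes)
    return KstResult(1.0 - k_s / k_t, k_s, k_t, k_within, sizes)


def kst_permutation_test(
    alignment: SequenceAlignment,
    labels: Sequence[str],
    permutations: int = 999,
    seed: int | None = None,
) -> KstResult:
    """K_ST with a one-tailed permutation p-value.

    Labels are permuted holding group sizes fixed;
    p = (#{K_ST* >= K_ST_obs} + 1) / (m + 1), so p >= 1/(m+1) always.
    """
    if permutations < 99:
        raise StructureError("need at least 99 permutations")
    dist, lab_arr, pops = _prepare(alignment, labels)
    n = len(lab_arr)
    k_t = float(dist.sum() / (n * (n - 1)))
    k_s, k_within, sizes = _k_s(dist, lab_arr, pops)
    if k_t == 0.0:
        return KstResult(None, k_s, k_t, k_within, sizes, None, permutations, seed)
    obs = 1.0 - k_s / k_t
    rng = np.random.default_rng(seed)
    perm_vals = np.empty(permutations)
    lab_perm = lab_arr.copy()
    for m in range(permutations):
        rng.shuffle(lab_perm)
        ks_perm, _, _ = _k_s(dist, lab_perm, pops)
        perm_vals[m] = 1.0 - ks_perm / k_t
    b = int(np.sum(perm_vals >= obs))
    p = (b + 1) / (permutations + 1)
    return KstResult(
        obs,
        k_s,
        k_t,
        k_within,
        sizes,
        p=float(p),
        permutations=permutations,
        seed=seed,
        permutation_mean=float(perm_vals.mean()),
        permutation_q95=float(np.quantile(perm_vals, 0.95)),
    )
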