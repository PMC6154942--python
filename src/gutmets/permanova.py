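"""Permutational multivariate ANOVA (Adonis) and subsample saturation curves.

The pseudo-F statistic follows Anderson's sum-of-squares partition of the
squared distance matrix; significance comes from seed-deterministic label
permutations with the +1 correction, so p is never exactly zero and is
bounded below by 1/(n_permutations + 1).

The saturation procedure repeatedly subsamples the cohort at increasing
sizes (stratified to preserve the group ratio), re-runs the test on the
sliced distance matrix, and reports the smallest size at which every
replicate is significant — the sample-size power curve used to argue a
survey is large enough to see a microbiome-phenotype association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, bray_curtis
from .io import OtuTable

__all__ = ["PermanovaResult", "permanova", "SaturationResult", "saturation_curve"]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.p < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("permutation p-value below its attainable minimum")
        if self.pseudo_F < 0:
            raise ValueError("pseudo-F must be non-negative")

    @property
    def log10_inv_p(self) -> float:
        """Significance on the log10(1/p) axis used for saturation plots."""
        return float(-np.log10(self.p))


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    if (codes < 0).any():
        raise ValueError("group labels contain missing values")
    counts = np.bincount(codes)
    if len(uniques) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    return codes, len(uniques)


def _pseudo_f_batch(d2: np.ndarray, memberships: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for each column of one-hot membership stacks.

    ``memberships`` is (n, B*a) with the B permutations' one-hot group
    indicators concatenated; ``sizes`` the matching group sizes. Within-group
    sums of squared distances come from the quadratic form 1_g' D2 1_g / 2.
    """
    n = d2.shape[0]
    a = sizes.shape[1]
    ss_total = d2.sum() / (2.0 * n)
    e = d2 @ memberships  # n x (B*a)
    within_pairs = (memberships * e).sum(axis=0) / 2.0
    ss_within = (within_pairs.reshape(-1, a) / sizes).sum(axis=1)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    d2 = dist.values**2
    n = d2.shape[0]
    codes, a = _group_codes(groups)
    if len(codes) != n:
        raise ValueError("labels do not align with the distance matrix")

    def one_hot(c: np.ndarray) -> np.ndarray:
        m = np.zeros((n, a))
        m[np.arange(n), c] = 1.0
        return m

    sizes = np.bincount(codes, minlength=a).astype(float)
    f_obs = float(_pseudo_f_batch(d2, one_hot(codes), sizes[None, :])[0])

    rng = np.random.default_rng(seed)
    batch = 250  # keep the n x (batch*a) work matrix small
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        stack = np.zeros((n, b * a))
        for k in range(b):
            perm = rng.permutation(codes)
            stack[np.arange(n), k * a + perm] = 1.0
        f_perm = _pseudo_f_batch(d2, stack, np.tile(sizes, (b, 1)))
        exceed += int((f_perm >= f_obs - 1e-12).sum())
        done += b
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(pseudo_F=f_obs, p=p, n_permutations=n_perm, n_samples=n)


@dataclass
class SaturationResult:
    """Per-(size, replicate) PERMANOVA p-values and the saturation size."""

    sizes: list
    alpha: float
    pvalues: pd.DataFrame  # columns: size, replicate, pseudo_F, p
    saturation_size: int | None = None

    def fraction_significant(self) -> pd.Series:
        return (
            self.pvalues.assign(sig=lambda d: d["p"] <= self.alpha)
            .groupby("size")["sig"]
            .mean()
        )


def _stratified_subsample(
    codes: np.ndarray, size: int, rng: np.random.Generator, max_retries: int = 20
) -> np.ndarray:
    """Random subsample of indices preserving the group ratio."""
    n = len(codes)
    a = codes.max() + 1
    counts = np.bincount(codes, minlength=a)
    target = np.maximum(2, np.floor(size * counts / n).astype(int))
    # settle rounding so the total matches exactly, never emptying a group
    guard = 0
    while target.sum() != size and guard < max_retries * a:
        if target.sum() < size:
            slack = np.flatnonzero(target < counts)
            target[slack[np.argmax((counts - target)[slack])]] += 1
        else:
            slack = np.flatnonzero(target > 2)
            if slack.size == 0:
                break
            target[slack[np.argmax(target[slack])]] -= 1
        guard += 1
    if target.sum() != size or (target < 2).any() or (target > counts).any():
        raise ValueError("cannot draw a subsample keeping every group")
    picks = [
        rng.choice(np.flatnonzero(codes == g), size=target[g], replace=False)
        for g in range(a)
    ]
    return np.sort(np.concatenate(picks))


def saturation_curve(
    table: OtuTable,
    groups,
    sizes,
    replicates: int = 50,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    dist: DistanceMatrix | None = None,
) -> SaturationResult:
    """Significance-saturation curve over subsample sizes.

    For each size, ``replicates`` stratified subsamples are drawn, the
    Bray-Curtis matrix is sliced to the subsample, and PERMANOVA is run.
    Reports all p-values and the smallest size at which every replicate
    reaches ``p <= alpha`` (None if never).
    """
    sizes = sorted(int(s) for s in sizes)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    codes, _ = _group_codes(groups)
    if dist is None:
        dist = bray_curtis(table)
    n = len(dist.sample_ids)
    if sizes[-1] > n:
        raise ValueError("max size exceeds the number of samples")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(replicates):
            if size == n:
                idx = np.arange(n)
            else:
                idx = _stratified_subsample(codes, size, rng)
            res = permanova(
                dist.submatrix(idx),
                codes[idx],
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {"size": size, "replicate": rep, "pseudo_F": res.pseudo_F, "p": res.p}
            )
    pvals = pd.DataFrame(rows)
    saturated = None
    for size in sizes:
        sub = pvals.loc[pvals["size"] == size, "p"]
        if (sub <= alpha).all():
            saturated = size
            break
    return SaturationResult(
        sizes=sizes, alpha=alpha, pvalues=pvals, saturation_size=saturated
    )
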