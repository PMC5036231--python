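"""Permutation test of parental-contribution clustering.

Case dogs that share sires (or dams) more often than random draws from
the cohort point to a familial, possibly genetic, component of disease
risk.  The statistic summarises how concentrated a dog sample's parents
are on one axis: group the sampled dogs by sire (or dam) with counts
c_1..c_k over the k contributing parents, then

* ``offspring_weighted`` (default): sum(c_i^2) / sum(c_i) — the average
  sibship size experienced by a sampled dog, i.e. each parent weighted
  by its contribution;
* ``plain_mean``: n / k — offspring per contributing parent.

Both equal 1 when every parent contributes one dog and n when a single
parent accounts for the whole sample.  The null distribution is built
from repeated simple random samples (without replacement) of the same
size drawn from the full cohort; the upper-tail p-value uses the
add-one rule p = (1 + #{null >= observed}) / (n_perm + 1), so the
smallest attainable p is 1/(n_perm+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContributionSummary",
    "PermutationResult",
    "ExhaustiveNull",
    "contribution_statistic",
    "permutation_test",
    "exhaustive_null",
]

_AXES = ("sire", "dam")
_WEIGHTINGS = ("offspring_weighted", "plain_mean")


@dataclass(frozen=True)
class ContributionSummary:
    parent_axis: str
    counts: tuple[int, ...]  # offspring per contributing parent, descending
    n_parents: int
    n_dogs: int
    statistic: float
    weighting: str
    n_excluded: int = 0  # dogs dropped for an unknown parent on this axis


@dataclass
class PermutationResult:
    observed: ContributionSummary
    null_values: np.ndarray
    pct_2_5: float
    pct_97_5: float
    p_value: float
    n_perm: int
    seed: int

    @property
    def significant_clustering(self) -> bool:
        """Observed statistic beyond the upper 97.5th centile of the null."""
        return self.observed.statistic > self.pct_97_5


def _parent_series(pedigree: pd.DataFrame, parent_axis: str) -> pd.Series:
    if parent_axis not in _AXES:
        raise ValueError(f"parent_axis must be one of {_AXES}, got {parent_axis!r}")
    col = f"{parent_axis}_id"
    if col not in pedigree.columns or "dog_id" not in pedigree.columns:
        raise ValueError(f"pedigree needs columns dog_id and {col}")
    s = pedigree.set_index("dog_id")[col]
    if s.index.has_duplicates:
        raise ValueError("duplicate dog_id in pedigree")
    return s.replace("", np.nan)


def _stat(counts: np.ndarray, weighting: str) -> float:
    n = int(counts.sum())
    if weighting == "offspring_weighted":
        return float((counts.astype(np.float64) ** 2).sum() / n)
    if weighting == "plain_mean":
        return n / len(counts)
    raise ValueError(f"weighting must be one of {_WEIGHTINGS}, got {weighting!r}")


def contribution_statistic(
    dog_ids: Iterable,
    pedigree: pd.DataFrame,
    parent_axis: str = "sire",
    weighting: str = "offspring_weighted",
) -> ContributionSummary:
    """Concentration of parental contributions within a dog sample."""
    parents = _parent_series(pedigree, parent_axis)
    ids = pd.Index(list(dog_ids))
    missing = ids.difference(parents.index)
    if len(missing):
        raise KeyError(f"dogs absent from pedigree: {list(missing)[:5]}")
    sel = parents.loc[ids]
    n_excluded = int(sel.isna().sum())
    sel = sel.dropna()
    if sel.empty:
        raise ValueError("no sampled dog has a known parent on this axis")
    counts = np.sort(sel.value_counts().to_numpy())[::-1]
    return ContributionSummary(
        parent_axis=parent_axis,
        counts=tuple(int(c) for c in counts),
        n_parents=len(counts),
        n_dogs=int(counts.sum()),
        statistic=_stat(counts, weighting),
        weighting=weighting,
        n_excluded=n_excluded,
    )


def _codes_for(pedigree: pd.DataFrame, cohort_ids, parent_axis: str):
    """(parent codes per cohort dog with known parent, kept ids, n dropped)."""
    parents = _parent_series(pedigree, parent_axis)
    ids = pd.Index(list(cohort_ids))
    missing = ids.difference(parents.index)
    if len(missing):
        raise KeyError(f"dogs absent from pedigree: {list(missing)[:5]}")
    sel = parents.loc[ids]
    kept = sel.dropna()
    codes, _ = pd.factorize(kept.to_numpy())
    return codes.astype(np.int64), kept.index, len(ids) - len(kept)


def _null_stats(
    codes: np.ndarray, m: int, n_perm: int, rng: np.random.Generator, weighting: str
) -> np.ndarray:
    n = len(codes)
    n_parents = int(codes.max()) + 1
    out = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(n, size=m, replace=False)
        counts = np.bincount(codes[pick], minlength=n_parents)
        counts = counts[counts > 0]
        out[i] = _stat(counts, weighting)
    return out


def permutation_test(
    case_ids: Iterable,
    cohort_ids: Iterable,
    pedigree: pd.DataFrame,
    parent_axis: str = "sire",
    n_perm: int = 10_000,
    seed: int = 0,
    weighting: str = "offspring_weighted",
    tie_break: str = "conservative",
) -> PermutationResult:
    """Monte-Carlo permutation test of parental clustering among cases.

    Draws ``n_perm`` random samples of the case-set size from the cohort
    and compares the observed contribution statistic with the resulting
    null.  Dogs with an unknown parent on the chosen axis are dropped
    from both the case set and the sampling frame (counted in the
    observed summary's ``n_excluded``).

    ``tie_break`` controls how null draws exactly equal to the observed
    statistic enter the p-value.  ``"conservative"`` (default) counts
    every tie as at least as extreme — valid but super-uniform for a
    discrete statistic.  ``"random"`` places the observed value at a
    uniformly random rank within its tie block, which makes the null
    distribution of p exactly uniform on the add-one grid; use it for
    calibration studies, not for reporting.
    """
    case_set = set(case_ids)
    cohort_list = list(dict.fromkeys(cohort_ids))
    if not case_set <= set(cohort_list):
        raise ValueError("case_ids must be a subset of cohort_ids")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes, kept_ids, _n_dropped = _codes_for(pedigree, cohort_list, parent_axis)
    kept_cases = [d for d in kept_ids if d in case_set]
    m = len(kept_cases)
    if m == 0:
        raise ValueError("no case dog has a known parent on this axis")
    observed = contribution_statistic(kept_cases, pedigree, parent_axis, weighting)
    observed = ContributionSummary(
        **{**observed.__dict__, "n_excluded": len(case_set) - m}
    )
    rng = np.random.default_rng(seed)
    null = _null_stats(codes, m, n_perm, rng, weighting)
    n_greater = int((null > observed.statistic + 1e-12).sum())
    n_tied = int((np.abs(null - observed.statistic) <= 1e-12).sum())
    if tie_break == "conservative":
        p = (1 + n_greater + n_tied) / (n_perm + 1)
    elif tie_break == "random":
        p = (1 + n_greater + int(rng.integers(0, n_tied + 1))) / (n_perm + 1)
    else:
        raise ValueError(f"tie_break must be conservative/random, got {tie_break!r}")
    lo, hi = np.percentile(null, [2.5, 97.5])
    return PermutationResult(
        observed=observed,
        null_values=null,
        pct_2_5=float(lo),
        pct_97_5=float(hi),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class ExhaustiveNull:
    values: np.ndarray  # statistic for every subset, sorted ascending
    case_size: int
    n_subsets: int
    parent_axis: str
    weighting: str

    def tail_p(self, observed: float) -> float:
        """Exact upper-tail probability P(S >= observed) over all subsets."""
        return float((self.values >= observed - 1e-12).mean())


def exhaustive_null(
    case_size: int,
    cohort_ids: Sequence,
    pedigree: pd.DataFrame,
    parent_axis: str = "sire",
    weighting: str = "offspring_weighted",
    max_subsets: int = 10**6,
) -> ExhaustiveNull:
    """Full null distribution by enumerating every subset of the cohort.

    Brute-force oracle for the Monte-Carlo sampler; refuses when
    C(cohort, case_size) exceeds ``max_subsets``.
    """
    codes, kept_ids, _ = _codes_for(pedigree, cohort_ids, parent_axis)
    n = len(codes)
    if not 1 <= case_size <= n:
        raise ValueError(f"case_size must be in [1, {n}]")
    n_subsets = math.comb(n, case_size)
    if n_subsets > max_subsets:
        raise ValueError(
            f"C({n}, {case_size}) = {n_subsets} subsets exceeds the "
            f"enumeration bound {max_subsets}"
        )
    n_parents = int(codes.max()) + 1
    vals = np.empty(n_subsets)
    for i, combo in enumerate(combinations(range(n), case_size)):
        counts = np.bincount(codes[list(combo)], minlength=n_parents)
        vals[i] = _stat(counts[counts > 0], weighting)
    vals.sort()
    return ExhaustiveNull(vals, case_size, n_subsets, parent_axis, weighting)
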