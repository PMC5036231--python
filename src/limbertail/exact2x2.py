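"""Exact conditional inference for 2x2 contingency tables.

Conditioning a 2x2 table on both margins leaves a single free cell whose
conditional distribution is Fisher's noncentral hypergeometric with
noncentrality equal to the odds ratio psi.  Everything in this module —
the conditional maximum-likelihood estimate, exact confidence intervals
(minimum-likelihood, Blaker and central orderings) and Fisher's exact
test — is computed from that one distribution, evaluated stably in log
space over the conditional support.

The table layout follows the case-control convention::

               exposed   unexposed
    cases        a           b
    controls     c           d

so the odds ratio compares the odds of exposure among cases with the
odds among controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable2x2",
    "OrEstimate",
    "conditional_mle_or",
    "exact_or_ci",
    "fisher_exact_p",
    "exact_or_estimate",
]

# relative tolerance for "as or less probable" ties, matching the
# convention of R's fisher.test
_TIE_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-status counts: a/b are exposed/unexposed cases,
    c/d exposed/unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    def swap_exposure(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.b, self.a, self.d, self.c)


@dataclass
class OrEstimate:
    """Conditional-MLE odds ratio with an exact conditional CI."""

    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    level: float
    method: str  # CI/p ordering: "minlike", "blaker" or "central"
    boundary: bool = False  # point estimate on the boundary (zero cell)
    flags: list[str] = field(default_factory=list)


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    a, b, c, d = np.asarray(table).ravel()
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def _support(r1: int, r2: int, c1: int) -> np.ndarray:
    return np.arange(max(0, c1 - r2), min(r1, c1) + 1)


def _log_weights(ks: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log binomial weights of the conditional likelihood, psi-free part."""
    return (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
    )


def _pmf(ks: np.ndarray, logw: np.ndarray, log_psi: float) -> np.ndarray:
    lp = logw + ks * log_psi
    return np.exp(lp - logsumexp(lp))


def _check_margins(t: ContingencyTable2x2) -> None:
    r1, r2 = t.row_margins
    c1, c2 = t.col_margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(
            "odds ratio undefined: table has an empty margin "
            f"(rows {r1},{r2}; cols {c1},{c2})"
        )


def conditional_mle_or(table) -> float:
    """Conditional maximum-likelihood odds ratio.

    Maximises the noncentral hypergeometric likelihood of the observed
    table given both margins, equivalently solves E_psi[A] = a for the
    conditional mean, which is strictly increasing in log psi.  Returns
    0.0 / inf when the observed count sits on the boundary of the
    conditional support (a zero cell).
    """
    t = _as_table(table)
    _check_margins(t)
    r1, r2 = t.row_margins
    c1 = t.a + t.c
    ks = _support(r1, r2, c1)
    if len(ks) == 1:
        # margins determine the table; OR not estimable, return 1 by convention
        return 1.0
    if t.a == ks[0]:
        return 0.0
    if t.a == ks[-1]:
        return math.inf
    logw = _log_weights(ks, r1, r2, c1)

    def mean_minus_a(log_psi: float) -> float:
        return float(_pmf(ks, logw, log_psi) @ ks) - t.a

    lo, hi = -1.0, 1.0
    while mean_minus_a(lo) > 0:
        lo *= 2.0
    while mean_minus_a(hi) < 0:
        hi *= 2.0
    return math.exp(brentq(mean_minus_a, lo, hi, xtol=1e-12, rtol=1e-14))


def _tail_probs(ks, logw, a: int, log_psi: float) -> tuple[float, float]:
    """(P[A <= a], P[A >= a]) under psi."""
    p = _pmf(ks, logw, log_psi)
    i = int(np.searchsorted(ks, a))
    return float(p[: i + 1].sum()), float(p[i:].sum())


def _p_two_sided(ks, logw, a: int, log_psi: float, method: str) -> float:
    p = _pmf(ks, logw, log_psi)
    i = int(np.searchsorted(ks, a))
    if method == "minlike":
        return float(p[p <= p[i] * (1 + _TIE_EPS)].sum())
    if method == "blaker":
        lower, upper = float(p[: i + 1].sum()), float(p[i:].sum())
        if upper <= lower:
            F = np.cumsum(p)
            opp = F[F <= upper * (1 + _TIE_EPS)]
            return upper + (float(opp[-1]) if len(opp) else 0.0)
        S = np.cumsum(p[::-1])[::-1]
        opp = S[S <= lower * (1 + _TIE_EPS)]
        return lower + (float(opp[0]) if len(opp) else 0.0)
    if method == "central":
        lower, upper = float(p[: i + 1].sum()), float(p[i:].sum())
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown method {method!r}")


def fisher_exact_p(table, alternative: str = "two_sided", method: str = "minlike") -> float:
    """Fisher's exact test p-value at psi = 1.

    The two-sided p sums the probability of every table (with the same
    margins) as or less probable than the one observed — the
    minimum-likelihood ordering used by standard implementations.
    One-sided alternatives are plain conditional tail sums.
    """
    t = _as_table(table)
    r1, r2 = t.row_margins
    c1 = t.a + t.c
    ks = _support(r1, r2, c1)
    logw = _log_weights(ks, r1, r2, c1)
    if alternative == "two_sided":
        return min(1.0, _p_two_sided(ks, logw, t.a, 0.0, method))
    lower, upper = _tail_probs(ks, logw, t.a, 0.0)
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    raise ValueError(f"unknown alternative {alternative!r}")


def _solve_decreasing(f, target: float) -> float:
    """Root of f(log_psi) = target for f decreasing in log_psi."""
    g = lambda x: f(x) - target
    lo, hi = -1.0, 1.0
    while g(lo) < 0:
        lo *= 2.0
        if lo < -500:
            return -math.inf
    while g(hi) > 0:
        hi *= 2.0
        if hi > 500:
            return math.inf
    return brentq(g, lo, hi, xtol=1e-11, rtol=1e-13)


def exact_or_ci(table, level: float = 0.95, method: str = "minlike") -> tuple[float, float]:
    """Exact conditional confidence interval for the odds ratio.

    ``method="minlike"`` (default) inverts the two-sided
    minimum-likelihood-ordered exact test, the companion of the
    two-sided Fisher p-value; ``"blaker"`` inverts Blaker's combined
    tails; ``"central"`` inverts two one-sided tests at (1-level)/2
    each, giving the classical central interval.  Zero cells yield
    one-sided intervals with a 0 or inf endpoint.
    """
    t = _as_table(table)
    _check_margins(t)
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    r1, r2 = t.row_margins
    c1 = t.a + t.c
    ks = _support(r1, r2, c1)
    if len(ks) == 1:
        return (0.0, math.inf)
    logw = _log_weights(ks, r1, r2, c1)

    if method == "central":
        # P[A >= a] increases with psi, P[A <= a] decreases
        if t.a == ks[0]:
            low = 0.0
        else:
            x = _solve_decreasing(lambda lp: -_tail_probs(ks, logw, t.a, lp)[1], -alpha / 2)
            low = math.exp(x) if math.isfinite(x) else (0.0 if x < 0 else math.inf)
        if t.a == ks[-1]:
            high = math.inf
        else:
            x = _solve_decreasing(lambda lp: _tail_probs(ks, logw, t.a, lp)[0], alpha / 2)
            high = math.exp(x) if math.isfinite(x) else (0.0 if x < 0 else math.inf)
        return (low, high)

    if method not in ("minlike", "blaker"):
        raise ValueError(f"unknown method {method!r}")

    # two-sided orderings: p(psi) rises to 1 near the MLE and falls
    # towards both boundaries; endpoints are the outermost alpha-crossings.
    # For a boundary count the maximum sits at psi -> 0 (or inf).
    pfun = lambda lp: _p_two_sided(ks, logw, t.a, lp, method)
    mle = conditional_mle_or(t)
    if 0 < mle < math.inf:
        centre = math.log(mle)
    else:
        centre = 0.0
        step = -1.0 if mle == 0.0 else 1.0
        while pfun(centre) <= alpha and abs(centre) < 500:
            centre += step

    if t.a == ks[0]:
        low = 0.0
    else:
        lo = centre - 1.0
        while pfun(lo) > alpha:
            lo -= 1.0
            if lo < -500:
                break
        low = math.exp(brentq(lambda lp: pfun(lp) - alpha, lo, centre)) if lo >= -500 else 0.0
    if t.a == ks[-1]:
        high = math.inf
    else:
        hi = centre + 1.0
        while pfun(hi) > alpha:
            hi += 1.0
            if hi > 500:
                break
        high = math.exp(brentq(lambda lp: pfun(lp) - alpha, centre, hi)) if hi <= 500 else math.inf
    return (low, high)


def exact_or_estimate(table, level: float = 0.95, method: str = "minlike") -> OrEstimate:
    """Bundle conditional-MLE point estimate, exact CI and exact p."""
    t = _as_table(table)
    point = conditional_mle_or(t)
    low, high = exact_or_ci(t, level=level, method=method)
    p = fisher_exact_p(t, "two_sided", method=method if method != "central" else "central")
    boundary = not (0.0 < point < math.inf)
    flags = ["boundary_estimate"] if boundary else []
    return OrEstimate(point, low, high, p, level, method, boundary, flags)
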