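"""Group-level statistics for paired-language laterality cohorts.

Covers split-half (odd/even trial) reliability, Spearman association
between L1 and L2 LIs, Bland-Altman style equivalence against a +/-2.5
repeatability bound, one-sample and Welch two-sample t-tests, the
early/late age-of-acquisition split, and the default-prior (JZS) Bayes
factor for the paired t-test.

The JZS Bayes factor for the one-sample test on the paired differences
is

    BF10 = [ integral (1 + n g)^{-1/2}
             (1 + t^2 / ((1 + n g) nu))^{-(nu+1)/2} pi(g) dg ]
           / (1 + t^2 / nu)^{-(nu+1)/2}

where nu = n - 1 and pi(g) is the inverse-gamma(1/2, r^2/2) mixing
density equivalent to a Cauchy(0, r) prior on the standardized effect
size.  The integral is evaluated by adaptive quadrature after the
substitution g = u / (1 - u).  The default scale r = sqrt(2)/2 matches
the common "medium" default.  BF01 = 1 / BF10 quantifies evidence for
the null of equal means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sps

from .laterality import grand_average, li_mean
from .preprocess import EpochSet

DEFAULT_RSCALE = np.sqrt(2.0) / 2.0
DEFAULT_EQUIVALENCE_BOUND = 2.5


# ---------------------------------------------------------------------------
# split-half reliability


def split_half_li(es: EpochSet, poi) -> tuple[float, float]:
    """LI from odd-numbered and even-numbered trials separately.

    Parity follows 1-based trial numbering in presentation order, fixed
    before any exclusion (an excluded trial simply drops out of its
    parity class).  Returns ``(li_odd, li_even)``.
    """
    out = []
    for parity in (0, 1):  # 0-based index 0,2,... are odd 1-based trials
        sub = es.copy()
        drop = np.arange(sub.n_trials) % 2 != parity
        sub.included = sub.included & ~drop
        if sub.n_included == 0:
            raise ValueError(
                f"no included {'odd' if parity == 0 else 'even'} trials"
            )
        out.append(li_mean(grand_average(sub), sub.time_axis, poi))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# correlation and t-tests


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero variance in ranks: correlation undefined")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of ``mean(values) == mu0``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(v, popmean=mu0)
    return float(res.statistic), int(v.size - 1), float(res.pvalue)


def two_sample_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch (unequal-variance) two-sided two-sample t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups degenerate: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Bland-Altman style equivalence


@dataclass
class EquivalenceReport:
    """Agreement of paired LIs against a repeatability bound.

    If the two measures are equivalent, ~95% of difference scores should
    fall within ``(-bound, +bound)`` (the repeatability coefficient,
    mean zero +/- 1.96 SD; 2.5 for this task family).
    """

    diffs: np.ndarray
    bound: float
    prop_within: float
    n: int
    spearman_rho: float | None = None

    @property
    def equivalent(self) -> bool:
        return self.prop_within >= 0.95


def bland_altman_equivalence(
    li1, li2, bound: float = DEFAULT_EQUIVALENCE_BOUND
) -> EquivalenceReport:
    """Fraction of paired LI differences within ``+/- bound``."""
    a = np.asarray(li1, dtype=float)
    b = np.asarray(li2, dtype=float)
    if a.size != b.size:
        raise ValueError("paired lists must have equal length")
    if a.size == 0:
        raise ValueError("need at least one pair")
    diffs = a - b
    within = np.abs(diffs) <= bound
    rho = spearman(a, b) if a.size >= 3 and np.unique(a).size > 1 and np.unique(b).size > 1 else None
    return EquivalenceReport(
        diffs=diffs,
        bound=float(bound),
        prop_within=float(within.mean()),
        n=int(a.size),
        spearman_rho=rho,
    )


# ---------------------------------------------------------------------------
# JZS Bayes factor


@dataclass
class BayesFactorResult:
    """Default-prior Bayes factor for the paired t-test.

    ``bf10`` follows the R 'BayesFactor' printing convention (values
    below 1 favour the null of equal means); ``bf01`` is its reciprocal,
    evidence for the null.
    """

    bf01: float
    bf10: float
    t: float
    n: int
    rscale: float

    def __float__(self) -> float:
        return self.bf01


def _jzs_bf10_from_t(t: float, n: int, rscale: float) -> float:
    nu = n - 1

    def integrand(u: float) -> float:
        g = u / (1.0 - u)
        # inverse-gamma(1/2, r^2/2) density
        pi_g = (
            rscale
            / np.sqrt(2.0 * np.pi)
            * g ** (-1.5)
            * np.exp(-(rscale**2) / (2.0 * g))
        )
        like = (1.0 + n * g) ** -0.5 * (
            1.0 + t**2 / ((1.0 + n * g) * nu)
        ) ** (-(nu + 1) / 2.0)
        return like * pi_g / (1.0 - u) ** 2

    num, err = integrate.quad(
        integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-8, limit=500
    )
    if not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise ArithmeticError(
            f"Bayes factor quadrature failed (value={num}, abs err={err})"
        )
    den = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return num / den


def jzs_bf_paired(li1, li2, rscale: float = DEFAULT_RSCALE) -> BayesFactorResult:
    """JZS Bayes factor for equivalence of paired LI means.

    Runs the default-prior one-sample test on the paired differences and
    returns both directions; ``float()`` of the result is BF01 (evidence
    for the null of equal means).
    """
    a = np.asarray(li1, dtype=float)
    b = np.asarray(li2, dtype=float)
    if a.size != b.size:
        raise ValueError("paired lists must have equal length")
    n = int(a.size)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    bf10 = _jzs_bf10_from_t(t, n, rscale)
    return BayesFactorResult(bf01=1.0 / bf10, bf10=bf10, t=t, n=n, rscale=rscale)


# ---------------------------------------------------------------------------
# age of acquisition


def aoa_split(ages) -> np.ndarray:
    """Early/late age-of-acquisition labels: early iff age < 6 years."""
    a = np.asarray(ages, dtype=float)
    if (a < 0).any():
        raise ValueError("ages must be >= 0")
    return np.where(a < 6, "early", "late")
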