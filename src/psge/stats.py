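"""Follow-up statistics: Storer-Kim, hypergeometric overlap, 2x2 chi-square.

The Storer-Kim test is the exact *unconditional* test of equality of two
binomial proportions: the null probability of every outcome pair is
evaluated at the pooled proportion estimate and summed over outcomes at
least as extreme (by the pooled-variance z statistic) as the observed one.
It is used here to compare the numbers of maternally versus paternally
biased transcripts within a sample group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2, hypergeom

_Z_ATOL = 1e-12  # ties in |z| at floating-point resolution count as extreme


@dataclass(frozen=True)
class TwoProportionData:
    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError("counts must satisfy 0 <= x <= n")


@dataclass(frozen=True)
class OverlapData:
    universe: int
    k1: int
    k2: int
    overlap: int

    def __post_init__(self):
        if not (0 <= self.k1 <= self.universe and 0 <= self.k2 <= self.universe):
            raise ValueError("list sizes must lie within the universe")
        if not (0 <= self.overlap <= min(self.k1, self.k2)):
            raise ValueError("overlap must satisfy 0 <= o <= min(k1, k2)")


@lru_cache(maxsize=128)
def _z_grid(n1: int, n2: int) -> np.ndarray:
    """Pooled-variance z statistic for every outcome pair (y1, y2)."""
    y1 = np.arange(n1 + 1)[:, None]
    y2 = np.arange(n2 + 1)[None, :]
    pooled = (y1 + y2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (y1 / n1 - y2 / n2) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)  # pooled estimate 0 or 1 => z := 0


def storer_kim_test(data: TwoProportionData, alternative: str = "two_sided") -> float:
    """Exact unconditional p-value for H0: p1 = p2.

    Outcome probabilities are binomial at the pooled estimate
    p_hat = (x1+x2)/(n1+n2); a pair (y1, y2) is at least as extreme as the
    observed data when |z(y)| >= |z(x)| (two-sided) or z(y) >= z(x)
    (``greater``, i.e. p1 > p2).  Returns p in (0, 1].
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x1, n1, x2, n2 = data.x1, data.n1, data.x2, data.n2
    p_hat = (x1 + x2) / (n1 + n2)
    z = _z_grid(n1, n2)
    z_obs = z[x1, x2]
    if alternative == "two_sided":
        extreme = np.abs(z) >= np.abs(z_obs) - _Z_ATOL
    else:
        extreme = z >= z_obs - _Z_ATOL
    if extreme.all():
        return 1.0  # every outcome is at least as extreme (e.g. z_obs = 0)
    prob = np.outer(binom.pmf(np.arange(n1 + 1), n1, p_hat), binom.pmf(np.arange(n2 + 1), n2, p_hat))
    return float(min(1.0, prob[extreme].sum()))


def hypergeom_overlap_test(data: OverlapData) -> float:
    """Inclusive upper-tail hypergeometric p-value P[X >= o].

    X counts the overlap of a random size-k2 draw with a fixed size-k1 list
    in a universe of size N; symmetric in (k1, k2).
    """
    return float(min(1.0, hypergeom.sf(data.overlap - 1, data.universe, data.k1, data.k2)))


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    dof: int
    expected: np.ndarray
    low_expected_count: bool  # any expected cell count < 5


def chisq_2x2(table, continuity_correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square for a 2x2 table against the chi-square(1) reference.

    Emits a warning (and sets ``low_expected_count``) when any expected cell
    is below 5; zero margins are an error.
    """
    from scipy.stats import chi2_contingency

    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square is undefined with a zero margin")
    stat, p, dof, expected = chi2_contingency(obs, correction=continuity_correction)
    low = bool((expected < 5).any())
    if low:
        warnings.warn(
            "chi-square approximation unreliable: expected cell count < 5", UserWarning, stacklevel=2
        )
    return ChiSquareResult(float(stat), float(p), int(dof), expected, low)


def overlap_matrix(biased: dict, tested: dict) -> pd.DataFrame:
    """Pairwise hypergeometric overlap of biased-transcript lists.

    ``biased`` and ``tested`` map sample group -> set of transcript ids.  For
    each group pair the universe is the transcripts tested in *both* groups;
    each list is intersected with that shared universe before testing.
    """
    rows = []
    for g1, g2 in combinations(sorted(tested), 2):
        universe = tested[g1] & tested[g2]
        l1 = biased.get(g1, set()) & universe
        l2 = biased.get(g2, set()) & universe
        o = len(l1 & l2)
        if universe and (l1 or l2):
            p = hypergeom_overlap_test(OverlapData(len(universe), len(l1), len(l2), o))
        else:
            p = 1.0
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "shared_universe": len(universe),
                "n_biased_1": len(l1),
                "n_biased_2": len(l2),
                "overlap": o,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group1", "group2", "shared_universe", "n_biased_1", "n_biased_2", "overlap", "p_value"],
    )


def membership_chisq(
    biased_ids: set, unbiased_ids: set, members: set, continuity_correction: bool = False
) -> ChiSquareResult:
    """2x2 chi-square of {biased vs not} x {in membership list vs not}.

    Used e.g. to test whether parentally biased transcripts are enriched for
    mitochondria-localized genes; the membership list is user-supplied.
    """
    table = [
        [len(biased_ids & members), len(biased_ids - members)],
        [len(unbiased_ids & members), len(unbiased_ids - members)],
    ]
    return chisq_2x2(table, continuity_correction=continuity_correction)


def read_membership_list(path: str) -> set:
    """Plain-text gene list, one identifier per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
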