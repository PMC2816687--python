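"""Linked-vs-unlinked FST contrast via the Mann-Whitney U test.

Compares per-locus Hudson FST between colour-pattern-linked loci and
unlinked controls for one population pair, reporting class means +/- sd and
a two-sided Mann-Whitney p. Small samples get an exact midrank-permutation
p by full enumeration; larger ones the normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .popgen import PairwiseFst

logger = logging.getLogger("hzscan")

EXACT_LIMIT = 14  # full enumeration up to n1 + n2 of this size


@dataclass
class FstComparison:
    pop_pair: str
    linked: list[float]
    unlinked: list[float]
    mean_linked: float
    sd_linked: float
    mean_unlinked: float
    sd_unlinked: float
    U: float
    p: float
    n_na_excluded: int = 0
    linked_regions: tuple[str, ...] = field(default=("HmYb", "HmB"))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U (midranks) with exact or corrected-normal p.

    U is the statistic for ``x`` (midrank sum minus n1(n1+1)/2). When
    n1 + n2 <= EXACT_LIMIT the p-value is exact by enumerating all
    C(n1+n2, n1) group labelings of the pooled midranks (which handles ties
    exactly); otherwise the normal approximation with tie correction and a
    0.5 continuity correction is used. Two-sided p measures |U - n1 n2 / 2|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    if n1 + n2 <= EXACT_LIMIT:
        p = _exact_p(ranks, n1, U, mu, alternative)
    else:
        _, counts = np.unique(pooled, return_counts=True)
        N = n1 + n2
        tie_term = ((counts**3 - counts).sum()) / (N * (N - 1))
        sigma2 = n1 * n2 / 12 * (N + 1 - tie_term)
        if sigma2 <= 0:
            return U, 1.0
        sigma = math.sqrt(sigma2)
        if alternative == "two-sided":
            z = (abs(U - mu) - 0.5) / sigma
            p = 2 * stats.norm.sf(max(z, 0.0))
        elif alternative == "greater":
            p = stats.norm.sf((U - mu - 0.5) / sigma)
        elif alternative == "less":
            p = stats.norm.sf((mu - U - 0.5) / sigma)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        p = float(min(1.0, p))
    return U, p


def _exact_p(ranks: np.ndarray, n1: int, U_obs: float, mu: float,
             alternative: str) -> float:
    offset = n1 * (n1 + 1) / 2
    eps = 1e-9
    hits = total = 0
    for combo in itertools.combinations(range(len(ranks)), n1):
        U = ranks[list(combo)].sum() - offset
        total += 1
        if alternative == "two-sided":
            hits += abs(U - mu) >= abs(U_obs - mu) - eps
        elif alternative == "greater":
            hits += U >= U_obs - eps
        elif alternative == "less":
            hits += U <= U_obs + eps
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return hits / total


def compare_fst_classes(
    fst_table: Sequence[PairwiseFst],
    linked_regions: Sequence[str] = ("HmYb", "HmB"),
    alternative: str = "two-sided",
) -> FstComparison:
    """Class means +/- sd (n-1 denominator) and the Mann-Whitney contrast.

    Loci with NaN FST are excluded (count reported). Raises when either
    class is empty after exclusion.
    """
    linked, unlinked, n_na = [], [], 0
    pops = set()
    for rec in fst_table:
        pops.add((rec.pop_a, rec.pop_b))
        if math.isnan(rec.fst):
            n_na += 1
        elif rec.region in linked_regions:
            linked.append(rec.fst)
        else:
            unlinked.append(rec.fst)
    if n_na:
        logger.info("FST comparison: %d locus/loci with NA FST excluded", n_na)
    if not linked or not unlinked:
        raise ValueError("both linked and unlinked classes must be non-empty")
    if len(pops) > 1:
        logger.warning("FST table mixes population pairs: %s", sorted(pops))
    U, p = mann_whitney_u(linked, unlinked, alternative=alternative)
    (pa, pb) = next(iter(pops)) if pops else ("pop_a", "pop_b")

    def _sd(v: list[float]) -> float:
        return float(np.std(v, ddof=1)) if len(v) > 1 else math.nan

    return FstComparison(
        pop_pair=f"{pa} vs {pb}",
        linked=linked, unlinked=unlinked,
        mean_linked=float(np.mean(linked)), sd_linked=_sd(linked),
        mean_unlinked=float(np.mean(unlinked)), sd_unlinked=_sd(unlinked),
        U=U, p=p, n_na_excluded=n_na, linked_regions=tuple(linked_regions),
    )
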