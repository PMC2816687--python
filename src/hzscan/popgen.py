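"""Per-locus diversity, neutrality, and between-population differentiation.

Nucleotide diversity (pi), Watterson's theta, Tajima's D with the
beta-distribution significance test, and Hudson's FST
(1 - Hw/Hb on mean pairwise differences). Missing calls (N) are handled by
pairwise deletion with per-pair length normalization; gap-containing columns
are excluded before any statistic is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import LocusAlignment
from .variants import MISSING

logger = logging.getLogger("hzscan")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": MISSING}


@dataclass
class TajimaComponents:
    """All intermediate quantities of Tajima's D and its beta significance test."""

    n: int
    S: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    pi_total: float  # mean pairwise differences per locus (count scale)
    theta_w: float  # S / a1, per locus
    D: float
    D_min: float
    D_max: float
    p: float


@dataclass
class LocusPopgen:
    locus_id: str
    population: str
    n_haplotypes: int
    length_analyzed: int
    S: int
    pi_per_bp: float
    theta_w_per_bp: float
    D: float
    D_pvalue: float


@dataclass
class PairwiseFst:
    locus_id: str
    pop_a: str
    pop_b: str
    Hw: float
    Hb: float
    fst: float  # 1 - Hw/Hb, unclamped (slightly negative values are reported)
    region: str = "unlinked"


def coded_alignment(
    aln: LocusAlignment, haplotype_subset: Sequence[str] | None = None
) -> np.ndarray:
    """Integer-coded alignment restricted to gap-free columns.

    Returns an (n_haplotypes, length_analyzed) int8 array with -1 for N.
    """
    if haplotype_subset is not None:
        aln = aln.subset(haplotype_subset)
    chars = np.array([list(s) for _, s in aln.sequences], dtype="U1")
    keep = ~(chars == "-").any(axis=0)
    trimmed = chars[:, keep]
    codes = np.full(trimmed.shape, MISSING, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[trimmed == base] = code
    return codes


def _pairwise_matrices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (differences, comparable columns) with pairwise deletion."""
    valid = codes != MISSING
    neq = codes[:, None, :] != codes[None, :, :]
    both = valid[:, None, :] & valid[None, :, :]
    D = (neq & both).sum(axis=-1)
    L = both.sum(axis=-1)
    return D, L


def mean_pairwise_diversity(codes: np.ndarray) -> float:
    """Mean over haplotype pairs of per-pair per-bp differences."""
    n = codes.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity needs >=2 haplotypes")
    D, L = _pairwise_matrices(codes)
    iu = np.triu_indices(n, k=1)
    d, length = D[iu], L[iu]
    ok = length > 0
    if not ok.any():
        raise ValueError("no comparable columns between any haplotype pair")
    return float(np.mean(d[ok] / length[ok]))


def nucleotide_diversity(
    aln: LocusAlignment, haplotype_subset: Sequence[str] | None = None
) -> float:
    """Nucleotide diversity pi per bp over gap-trimmed columns."""
    return mean_pairwise_diversity(coded_alignment(aln, haplotype_subset))


def count_segregating_sites(codes: np.ndarray) -> int:
    """Columns with >=2 distinct non-missing bases."""
    S = 0
    for col in codes.T:
        obs = col[col != MISSING]
        if len(np.unique(obs)) >= 2:
            S += 1
    return S


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def watterson_theta(S: int, n: int, length: int) -> float:
    """Watterson's estimator theta_W = S / (a1 * length), per bp."""
    if n < 2:
        raise ValueError("Watterson's theta needs n >= 2")
    return S / (harmonic(n) * length)


def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_components(n: int, S: int, pi_total: float) -> TajimaComponents:
    """Tajima's D from haplotype count, segregating sites, and mean pairwise
    differences (count scale), with the beta-test support bounds.

    The support of the beta approximation is the large-S range of D:
    the minimum is reached when every site is a singleton, the maximum when
    every site splits the sample as evenly as possible.
    """
    if n < 4:
        raise ValueError("Tajima's D variance terms degenerate for n < 4")
    if S < 1:
        raise ValueError("Tajima's D undefined for S = 0")
    k = tajima_constants(n)
    a1, e1, e2 = k["a1"], k["e1"], k["e2"]
    theta_w = S / a1
    D = (pi_total - theta_w) / math.sqrt(e1 * S + e2 * S * (S - 1))
    pi_max_per_site = n / (2 * (n - 1)) if n % 2 == 0 else (n + 1) / (2 * n)
    D_min = (2 / n - 1 / a1) / math.sqrt(e2)
    D_max = (pi_max_per_site - 1 / a1) / math.sqrt(e2)
    tc = TajimaComponents(
        n=n, S=S, pi_total=pi_total, theta_w=theta_w, D=D,
        D_min=D_min, D_max=D_max, p=math.nan, **k,
    )
    tc.p = tajima_beta_pvalue(tc)
    return tc


def tajimas_d(
    aln: LocusAlignment, haplotype_subset: Sequence[str] | None = None
) -> TajimaComponents:
    """Tajima's D (with beta p-value) for one locus alignment."""
    codes = coded_alignment(aln, haplotype_subset)
    n = codes.shape[0]
    S = count_segregating_sites(codes)
    pi_total = mean_pairwise_diversity(codes) * codes.shape[1]
    return tajima_components(n, S, pi_total)


def tajima_beta_pvalue(tc: TajimaComponents) -> float:
    """Two-tailed p for D under a beta distribution on [D_min, D_max].

    The beta shape parameters are moment-matched so the distribution has
    mean 0 and variance 1 on the support; p = 2 * min(F(D), 1 - F(D)).
    D outside the support by more than 1e-9 is clamped with a warning.
    """
    a, b = tc.D_min, tc.D_max
    if not (a < 0 < b):
        raise ValueError("beta support must straddle zero")
    D = tc.D
    if D < a - 1e-9 or D > b + 1e-9:
        logger.warning("D=%.6g outside beta support [%.6g, %.6g]; clamped", D, a, b)
    D = min(max(D, a), b)
    total = -a * b - 1  # alpha+beta from variance matching
    if total <= 0:
        return math.nan
    u = -a / (b - a)  # standardized mean
    shape_p = u * total
    shape_q = (1 - u) * total
    F = stats.beta.cdf(D, shape_p, shape_q, loc=a, scale=b - a)
    return float(min(1.0, 2 * min(F, 1 - F)))


def locus_popgen(
    aln: LocusAlignment,
    population: str,
    haplotype_subset: Sequence[str] | None = None,
) -> LocusPopgen:
    """Diversity and neutrality summary for one locus in one population.

    Tajima's D and its p-value are NaN when S = 0 or n < 4.
    """
    codes = coded_alignment(aln, haplotype_subset)
    n, L = codes.shape
    S = count_segregating_sites(codes)
    pi = mean_pairwise_diversity(codes)
    D = p = math.nan
    if S >= 1 and n >= 4:
        tc = tajima_components(n, S, pi * L)
        D, p = tc.D, tc.p
    elif S >= 1:
        logger.warning("locus %s/%s: n=%d < 4, Tajima's D not computed",
                       aln.locus_id, population, n)
    return LocusPopgen(
        locus_id=aln.locus_id, population=population, n_haplotypes=n,
        length_analyzed=L, S=S, pi_per_bp=pi,
        theta_w_per_bp=watterson_theta(S, n, L), D=D, D_pvalue=p,
    )


def hudson_fst(
    aln: LocusAlignment,
    pop_a_haps: Sequence[str],
    pop_b_haps: Sequence[str],
    pop_a: str = "pop_a",
    pop_b: str = "pop_b",
    weighted: bool = False,
) -> PairwiseFst:
    """Hudson's FST: 1 - Hw/Hb on mean pairwise differences.

    Hw is by default the unweighted average of the two within-population
    mean pairwise differences (set ``weighted`` to weight by pair counts);
    Hb averages over all cross-population haplotype pairs. Hb = 0 gives NaN.
    """
    if len(pop_a_haps) < 2 or len(pop_b_haps) < 2:
        raise ValueError("hudson_fst needs >=2 haplotypes per population")
    codes = coded_alignment(aln, list(pop_a_haps) + list(pop_b_haps))
    na = len(pop_a_haps)
    codes_a, codes_b = codes[:na], codes[na:]
    pi_a = mean_pairwise_diversity(codes_a)
    pi_b = mean_pairwise_diversity(codes_b)
    if weighted:
        wa = math.comb(len(pop_a_haps), 2)
        wb = math.comb(len(pop_b_haps), 2)
        Hw = (wa * pi_a + wb * pi_b) / (wa + wb)
    else:
        Hw = (pi_a + pi_b) / 2
    D, L = _pairwise_matrices(codes)
    d_ab, len_ab = D[:na, na:].ravel(), L[:na, na:].ravel()
    ok = len_ab > 0
    if not ok.any():
        raise ValueError("no comparable columns between the populations")
    Hb = float(np.mean(d_ab[ok] / len_ab[ok]))
    fst = math.nan if Hb == 0 else 1 - Hw / Hb
    return PairwiseFst(aln.locus_id, pop_a, pop_b, Hw, Hb, fst, aln.region)
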