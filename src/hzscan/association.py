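"""Genotype-by-phenotype trend tests with Bonferroni control.

The per-site statistic is the Armitage linear trend chi-square in its
score-test form, chi2 = n * r^2, where r is the Pearson correlation between
minor-allele dosage and phenotype score over pairwise-complete individuals;
the reference distribution is chi-square with 1 df. Both variables live on
the shared {0, 0.5, 1} scale, but the statistic is invariant to any affine
recoding of either axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import SampleRecord
from .variants import GenotypeMatrix

logger = logging.getLogger("hzscan")


@dataclass
class SiteAssociation:
    locus_id: str
    position: int  # 1-based (global when the locus is placed)
    n_used: int
    chi2: float
    p: float
    neg_log10_p: float
    significant: bool
    reason: str = ""  # non-empty when the test is NA (e.g. "monomorphic")


def score_phenotypes(
    samples: Sequence[SampleRecord],
    race_scores: Mapping[str, float] | None = None,
    heterozygote_ids: Sequence[str] = (),
) -> np.ndarray:
    """Phenotype-score vector (NaN = missing) aligned with ``samples``.

    Explicit per-individual scores take precedence. Individuals without one
    get their race's fixed score from ``race_scores`` (population -> 0.0 or
    1.0). ``heterozygote_ids`` overrides individuals to 0.5 — the rule for
    hybrids that carry the dominant colour-pattern allele but show linked
    evidence of heterozygosity.
    """
    het = set(heterozygote_ids)
    race_scores = race_scores or {}
    scores = np.full(len(samples), np.nan)
    for i, rec in enumerate(samples):
        if rec.individual_id in het:
            scores[i] = 0.5
        elif rec.phenotype_score is not None:
            scores[i] = rec.phenotype_score
        elif rec.population in race_scores:
            s = float(race_scores[rec.population])
            if s not in (0.0, 1.0):
                raise ValueError(
                    f"race score for {rec.population} must be 0.0 or 1.0, got {s}"
                )
            scores[i] = s
    n_missing = int(np.isnan(scores).sum())
    if n_missing:
        logger.info("%d individual(s) with missing phenotype excluded from testing",
                    n_missing)
    return scores


def trend_test(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    locus_id: str = "",
    position: int = 0,
    cutoff_neg_log10: float = math.inf,
) -> SiteAssociation:
    """Armitage trend test on pairwise-complete (dosage, phenotype) pairs.

    Returns an NA record (reason "monomorphic") when either vector has zero
    variance among complete pairs; never raises for degenerate data.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(dosage) & ~np.isnan(phenotype)
    x, y = dosage[ok], phenotype[ok]
    n = len(x)
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return SiteAssociation(locus_id, position, n, math.nan, math.nan,
                               math.nan, False, reason="monomorphic")
    r = float(np.corrcoef(x, y)[0, 1])
    chi2 = n * r * r
    p = float(stats.chi2.sf(chi2, df=1))
    nlp = float(-np.log10(p)) if p > 0 else math.inf
    return SiteAssociation(locus_id, position, n, chi2, p, nlp,
                           significant=nlp > cutoff_neg_log10)


def bonferroni_threshold(alpha: float, m_sites: int) -> float:
    """Bonferroni cutoff on the -log10 scale: -log10(alpha / m)."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if m_sites < 1:
        raise ValueError(f"m_sites must be >= 1, got {m_sites}")
    return float(-math.log10(alpha / m_sites))


def association_scan(
    gm: GenotypeMatrix,
    phenotypes: np.ndarray | None = None,
    alpha: float = 0.05,
    m_total: int | None = None,
) -> list[SiteAssociation]:
    """Trend test at every site of a genotype matrix, Bonferroni-corrected.

    The correction denominator is ``m_total`` when given (to correct jointly
    across several scans), else the number of testable (non-NA) sites in this
    scan. Results are sorted by (locus, position); significance uses a strict
    ``>`` against the -log10 cutoff.
    """
    if phenotypes is None:
        phenotypes = gm.phenotypes
    if phenotypes is None:
        raise ValueError("no phenotype vector available")
    phenotypes = np.asarray(phenotypes, dtype=float)
    raw = [
        trend_test(gm.dosage[:, j], phenotypes, site.locus_id, site.position)
        for j, site in enumerate(gm.sites)
    ]
    m = m_total if m_total is not None else sum(1 for r in raw if not r.reason)
    if m == 0:
        logger.warning("association scan: no testable sites")
        return []
    cutoff = bonferroni_threshold(alpha, m)
    for r in raw:
        r.significant = (not r.reason) and r.neg_log10_p > cutoff
    return sorted(raw, key=lambda r: (r.locus_id, r.position))
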