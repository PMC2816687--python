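"""Variant-site extraction and the dosage genotype matrix.

Alignment columns containing any gap are excluded wholesale (indel regions
are trimmed before analysis); ``N`` is treated as a missing call. Genotypes
are coded as minor-allele dosage on the {0, 0.5, 1} scale shared with the
phenotype scores, i.e. (copies of the minor allele) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import LocusAlignment, SampleRecord

logger = logging.getLogger("hzscan")

MISSING = -1  # haplotype call code for N


@dataclass
class VariantSite:
    """One analyzable polymorphic alignment column.

    ``alleles`` are ordered by descending frequency (ties broken
    alphabetically, so at maf 0.5 the alphabetically later allele is minor);
    ``hap_calls`` index into ``alleles`` with -1 for missing; ``maf`` is the
    total frequency of non-major alleles among non-missing calls, which for a
    biallelic (or condensed) site is the minor-allele frequency.
    """

    locus_id: str
    column: int  # 0-based alignment column
    global_pos: int | None
    alleles: list[str]
    hap_calls: np.ndarray  # int8, aligned with the alignment's haplotype order
    maf: float
    condensed: bool = False
    all_minors_common: bool = False  # condensation fell back to major-vs-rest

    @property
    def position(self) -> int | None:
        """1-based position: global when placed, locus-local otherwise."""
        return self.global_pos if self.global_pos is not None else self.column + 1


@dataclass
class GenotypeMatrix:
    """Individuals x sites minor-allele dosage matrix ({0, 0.5, 1}, NaN missing)."""

    individuals: list[str]
    sites: list[VariantSite]
    dosage: np.ndarray  # float, shape (n_individuals, n_sites)
    phenotypes: np.ndarray | None = None  # aligned with individuals, NaN missing

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("dosage shape does not match individuals x sites")

    @property
    def positions(self) -> list[int | None]:
        return [s.position for s in self.sites]

    @property
    def maf(self) -> np.ndarray:
        return np.array([s.maf for s in self.sites])

    def select_sites(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            self.individuals,
            [self.sites[i] for i in keep],
            self.dosage[:, keep],
            self.phenotypes,
        )


def _char_matrix(aln: LocusAlignment) -> np.ndarray:
    return np.array([list(s) for _, s in aln.sequences], dtype="U1")


def gapless_columns(aln: LocusAlignment) -> np.ndarray:
    """Indices of alignment columns containing no gap character."""
    chars = _char_matrix(aln)
    return np.flatnonzero(~(chars == "-").any(axis=0))


def call_variable_sites(aln: LocusAlignment) -> list[VariantSite]:
    """Polymorphic, gap-free columns of one alignment.

    A column is a site iff, among non-missing calls, at least two distinct
    bases are each observed at least once. Columns with any gap are skipped.
    """
    chars = _char_matrix(aln)
    sites = []
    for col in gapless_columns(aln):
        column = chars[:, col]
        observed = column[column != "N"]
        bases, counts = np.unique(observed, return_counts=True)
        if len(bases) < 2:
            continue
        order = sorted(range(len(bases)), key=lambda i: (-counts[i], bases[i]))
        alleles = [str(bases[i]) for i in order]
        sorted_counts = counts[order]
        index = {a: i for i, a in enumerate(alleles)}
        calls = np.array(
            [MISSING if ch == "N" else index[ch] for ch in column], dtype=np.int8
        )
        sites.append(
            VariantSite(
                locus_id=aln.locus_id,
                column=int(col),
                global_pos=aln.global_position(int(col)),
                alleles=alleles,
                hap_calls=calls,
                # count-ratio form avoids float noise around the 0.05 cutoff
                maf=float(sorted_counts[1:].sum() / sorted_counts.sum()),
            )
        )
    return sites


def condense_multiallelic(site: VariantSite, maf_threshold: float = 0.05) -> VariantSite:
    """Merge the non-major alleles of a multi-allelic site into one class.

    Sites whose rarest allele is below ``maf_threshold`` follow the standard
    rare-minor merging rule. Multi-allelic sites whose minor alleles are all
    common are still condensed major-vs-rest, but flagged
    (``all_minors_common``) so they can be excluded downstream. Biallelic
    sites pass through unchanged.
    """
    if len(site.alleles) <= 2:
        return site
    calls = site.hap_calls
    observed = calls[calls != MISSING]
    counts = np.bincount(observed, minlength=len(site.alleles))
    freqs = counts / counts.sum()
    rare_rule = freqs.min() < maf_threshold
    merged_label = "/".join(site.alleles[1:])
    new_calls = np.where(calls == MISSING, MISSING, np.minimum(calls, 1)).astype(np.int8)
    return replace(
        site,
        alleles=[site.alleles[0], merged_label],
        hap_calls=new_calls,
        maf=float(counts[1:].sum() / counts.sum()),
        condensed=True,
        all_minors_common=not rare_rule,
    )


def build_genotype_matrix(
    aln_sites: dict[str, list[VariantSite]],
    alignments: dict[str, LocusAlignment],
    samples: Sequence[SampleRecord],
) -> GenotypeMatrix:
    """Assemble the dosage matrix across loci for a set of individuals.

    Dosage is (minor-allele copies)/2 where "minor" means any non-major
    allele of the (condensed) site. If either haplotype call is missing the
    entry is missing. Individuals without both haplotypes at a locus get
    missing entries for all of that locus's sites (warning logged).
    """
    individuals = [s.individual_id for s in samples]
    all_sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for locus_id, sites in aln_sites.items():
        if not sites:
            continue
        aln = alignments[locus_id]
        hap_index = {name: i for i, name in enumerate(aln.names)}
        rows = []
        for rec in samples:
            h1, h2 = rec.haplotype_names
            rows.append((hap_index.get(h1), hap_index.get(h2)))
        n_excluded = sum(1 for a, b in rows if a is None or b is None)
        if n_excluded:
            logger.warning(
                "locus %s: %d individual(s) lack both haplotypes; entries set missing",
                locus_id, n_excluded,
            )
        for site in sites:
            col = np.full(len(samples), np.nan)
            for k, (a, b) in enumerate(rows):
                if a is None or b is None:
                    continue
                c1, c2 = site.hap_calls[a], site.hap_calls[b]
                if c1 == MISSING or c2 == MISSING:
                    continue
                col[k] = (int(c1 > 0) + int(c2 > 0)) / 2.0
            all_sites.append(site)
            columns.append(col)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(individuals), 0))
    )
    phen = np.array(
        [np.nan if s.phenotype_score is None else s.phenotype_score for s in samples]
    )
    return GenotypeMatrix(individuals, all_sites, dosage, phen)


def filter_informative(gm: GenotypeMatrix, maf_threshold: float = 0.05) -> GenotypeMatrix:
    """Retain sites with minor-allele frequency strictly above the threshold."""
    keep = [i for i, s in enumerate(gm.sites) if s.maf > maf_threshold]
    return gm.select_sites(keep)


def sites_for_alignments(
    alignments: Sequence[LocusAlignment], maf_threshold: float = 0.05
) -> dict[str, list[VariantSite]]:
    """Call and condense variant sites for every alignment."""
    return {
        aln.locus_id: [
            condense_multiallelic(s, maf_threshold) for s in call_variable_sites(aln)
        ]
        for aln in alignments
    }
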