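"""End-to-end drivers tying the modules together for the CLI and scripts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import association, compare, ld, popgen, variants
from .config import Thresholds
from .io import (
    LocusAlignment,
    SampleRecord,
    match_samples_to_alignment,
    read_locus_alignments,
    read_locus_table,
    read_sample_table,
)


@dataclass
class Dataset:
    alignments: list[LocusAlignment]
    samples: list[SampleRecord]


def load_dataset(
    alignment_paths: Sequence[str | Path],
    sample_path: str | Path,
    locus_path: str | Path | None = None,
) -> Dataset:
    meta = read_locus_table(locus_path) if locus_path else None
    alignments = read_locus_alignments(sorted(alignment_paths, key=str), meta)
    samples = read_sample_table(sample_path)
    return Dataset(alignments, samples)


def population_haplotypes(
    samples: Sequence[SampleRecord], aln: LocusAlignment, population: str
) -> list[str]:
    """Haplotype names of a population's individuals present at this locus."""
    kept, _ = match_samples_to_alignment(
        [s for s in samples if s.population == population], aln
    )
    return [h for s in kept for h in s.haplotype_names]


def run_popgen(
    ds: Dataset, pop_a: str, pop_b: str
) -> tuple[list[popgen.LocusPopgen], list[popgen.PairwiseFst]]:
    """Per-locus-per-population diversity rows and per-locus Hudson FST."""
    div_rows, fst_rows = [], []
    for aln in ds.alignments:
        haps = {p: population_haplotypes(ds.samples, aln, p) for p in (pop_a, pop_b)}
        for pop, hs in haps.items():
            if len(hs) >= 2:
                div_rows.append(popgen.locus_popgen(aln, pop, hs))
        if len(haps[pop_a]) >= 2 and len(haps[pop_b]) >= 2:
            fst_rows.append(
                popgen.hudson_fst(aln, haps[pop_a], haps[pop_b], pop_a, pop_b)
            )
    return div_rows, fst_rows


def genotype_matrix_for_samples(
    alignments: Sequence[LocusAlignment],
    samples: Sequence[SampleRecord],
    thresholds: Thresholds = Thresholds(),
    informative_only: bool = False,
) -> variants.GenotypeMatrix:
    """Call, condense, and assemble dosages restricted to these samples.

    Sites are called on the subset of haplotypes the samples contribute, so
    frequencies (and the informativeness filter) refer to the analysis
    sample, not the full file.
    """
    aln_by_id = {}
    site_map = {}
    for aln in alignments:
        kept, _ = match_samples_to_alignment(samples, aln)
        names = [h for s in kept for h in s.haplotype_names]
        if len(names) < 2:
            continue
        sub = aln.subset(names)
        aln_by_id[aln.locus_id] = sub
        site_map[aln.locus_id] = [
            variants.condense_multiallelic(s, thresholds.maf)
            for s in variants.call_variable_sites(sub)
        ]
    gm = variants.build_genotype_matrix(site_map, aln_by_id, samples)
    if informative_only:
        gm = variants.filter_informative(gm, thresholds.maf)
    return gm


def run_association(
    ds: Dataset,
    thresholds: Thresholds = Thresholds(),
    m_total: int | None = None,
) -> list[association.SiteAssociation]:
    """Trend-test scan over all samples that carry a phenotype score."""
    gm = genotype_matrix_for_samples(ds.alignments, ds.samples, thresholds)
    phen = association.score_phenotypes(ds.samples)
    return association.association_scan(gm, phen, thresholds.alpha, m_total)


def run_ld(
    ds: Dataset,
    populations: Sequence[str] | None = None,
    pool: bool = True,
    thresholds: Thresholds = Thresholds(),
) -> dict[str, list[ld.LDRecord]]:
    """Composite LD per population, or pooled across the named populations.

    Pooling concatenates the populations' individuals before computing
    dosages; at divergent sites this inflates LD — that inflation is the
    analysis signal, not an artifact.
    """
    if populations is None:
        populations = sorted({s.population for s in ds.samples})
    groups: dict[str, list[SampleRecord]] = {}
    if pool:
        groups["+".join(populations)] = [
            s for s in ds.samples if s.population in populations
        ]
    else:
        for p in populations:
            groups[p] = [s for s in ds.samples if s.population == p]
    out = {}
    for label, samples in groups.items():
        gm = genotype_matrix_for_samples(
            ds.alignments, samples, thresholds, informative_only=True
        )
        out[label] = ld.ld_matrix(gm, thresholds.ld_min_n)
    return out


def run_compare_fst(
    ds: Dataset, pop_a: str, pop_b: str,
    linked_regions: Sequence[str] = ("HmYb", "HmB"),
) -> compare.FstComparison:
    _, fst_rows = run_popgen(ds, pop_a, pop_b)
    return compare.compare_fst_classes(fst_rows, linked_regions)


def decay_bins(max_distance: float, width: float = 500.0) -> np.ndarray:
    """Regular distance-bin edges from 0 to just past max_distance."""
    n = int(np.ceil(max_distance / width)) + 1
    return np.arange(0, (n + 1) * width, width)
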