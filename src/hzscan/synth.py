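"""Synthetic two-population datasets and null-model samples.

The generator emulates the statistical structure of a hybrid-zone
resequencing study of two parapatric colour-pattern races:

* neutral sites whose allele frequency is shared between the populations
  (drawn once per site from a background distribution),
* "selected" sites with large between-population frequency differentials,
  up to fixation in one race with the alternate allele at high frequency
  in the other,
* haplotype-block LD among selected sites: sites whose global positions
  chain within ``block_length`` bp form a block, and within a block each
  haplotype draws one uniform variate shared by all block sites
  (comonotone coupling), which preserves every site's marginal frequency
  while maximizing positive within-block LD,
* diploids formed by random pairing within a population; admixed
  individuals carry one haplotype from each population's process and are
  phenotype-scored 0.5,
* a standard neutral coalescent (no recombination, infinite sites) for
  null-distribution calibration.

Defaults mirror the study conditions: 30 diploids per race plus 2 admixed
individuals, 8 colour-pattern-linked loci spanning ~15 kb each carrying
selected sites (three with near-fixed differentials, the rest moderate),
3 unlinked neutral controls, and 14 kb haplotype blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import LocusAlignment, LocusMeta, SampleRecord, write_fasta

BASES = np.array(list("ACGT"))


@dataclass
class LocusSpec:
    locus_id: str
    region: str  # HmYb / HmB / unlinked
    length: int  # bp
    n_neutral_sites: int
    offset: int | None  # genomic offset on the shared axis; None = unplaced


@dataclass
class SelectedSiteSpec:
    locus_id: str
    column: int  # 0-based
    p_a: float  # derived-allele frequency in population A
    p_b: float  # derived-allele frequency in population B


@dataclass
class SynthConfig:
    seed: int
    n_per_pop: int = 30
    n_admixed: int = 2
    pop_a: str = "aglaope"
    pop_b: str = "amaryllis"
    comparison: str = "agl_ama"
    loci: list[LocusSpec] = field(default_factory=list)
    selected_sites: list[SelectedSiteSpec] = field(default_factory=list)
    background_freq: tuple[float, float] = (0.1, 0.9)  # U(lo, hi) shared freq
    block_length: int = 14000  # bp; chaining distance for selected-site blocks
    missing_rate: float = 0.0  # per haplotype call at variant columns

    def __post_init__(self) -> None:
        for s in self.selected_sites:
            if not (0 <= s.p_a <= 1 and 0 <= s.p_b <= 1):
                raise ValueError(f"selected site {s}: frequencies must be in [0,1]")
        if self.block_length < 0:
            raise ValueError("block_length must be >= 0")


def default_config(seed: int) -> SynthConfig:
    """The default study conditions: an HmB-style scan.

    Eight linked loci at 2 kb spacing (selected-site span ~14.6 kb), each
    with two selected sites — near-fixed differentials at the three "peak"
    loci, moderate (0.5-0.7) elsewhere — plus three unlinked neutral loci.
    """
    linked_ids = ["slu7", "kinesin", "gpcr", "hmb4", "hmb5", "hmb6", "hmb7", "mrsp"]
    loci = [
        LocusSpec(lid, "HmB", length=600, n_neutral_sites=8, offset=2000 * i)
        for i, lid in enumerate(linked_ids)
    ]
    loci += [
        LocusSpec(f"ctrl{i}", "unlinked", length=600, n_neutral_sites=8, offset=None)
        for i in range(1, 4)
    ]
    differentials = {
        "slu7": [(0.0, 1.0), (0.05, 1.0)],
        "kinesin": [(0.05, 0.95), (0.1, 1.0)],
        "gpcr": [(0.0, 0.9), (0.1, 0.95)],
        "hmb4": [(0.2, 0.8), (0.25, 0.85)],
        "hmb5": [(0.2, 0.9), (0.3, 0.8)],
        "hmb6": [(0.25, 0.75), (0.2, 0.8)],
        "hmb7": [(0.3, 0.85), (0.25, 0.8)],
        "mrsp": [(0.2, 0.7), (0.3, 0.8)],
    }
    selected = [
        SelectedSiteSpec(lid, column, pa, pb)
        for lid, pairs in differentials.items()
        for column, (pa, pb) in zip((150, 450), pairs)
    ]
    return SynthConfig(seed=seed, loci=loci, selected_sites=selected)


def neutral_config(seed: int, n_loci: int = 11, n_sites: int = 8) -> SynthConfig:
    """All-neutral variant of the default conditions (no selected sites).

    Loci are generated fresh (region HmB with 2 kb spacing for the first
    eight, unlinked after that, mirroring the default layout) so null
    calibrations can ask for as many sites as they need.
    """
    cfg = default_config(seed)
    loci = [
        LocusSpec(
            f"n{i:02d}",
            "HmB" if i < 8 else "unlinked",
            length=600,
            n_neutral_sites=n_sites,
            offset=2000 * i if i < 8 else None,
        )
        for i in range(n_loci)
    ]
    return replace(cfg, loci=loci, selected_sites=[], n_admixed=0)


@dataclass
class SimulatedDataset:
    alignments: list[LocusAlignment]
    samples: list[SampleRecord]
    locus_meta: dict[str, LocusMeta]
    selected_positions: list[tuple[str, int]]  # (locus_id, 1-based position)
    blocks: list[list[tuple[str, int]]]  # selected sites grouped by block


def _assign_blocks(
    cfg: SynthConfig, loci: dict[str, LocusSpec]
) -> list[list[SelectedSiteSpec]]:
    """Chain selected sites within block_length on the global axis."""
    placed, unplaced = [], []
    for s in cfg.selected_sites:
        off = loci[s.locus_id].offset
        if off is None:
            unplaced.append(s)
        else:
            placed.append((off + s.column, s))
    placed.sort(key=lambda t: t[0])
    blocks: list[list[SelectedSiteSpec]] = []
    last_pos = None
    for pos, s in placed:
        if last_pos is not None and pos - last_pos <= cfg.block_length:
            blocks[-1].append(s)
        else:
            blocks.append([s])
        last_pos = pos
    blocks.extend([s] for s in unplaced)
    return blocks


def simulate_two_pop_dataset(cfg: SynthConfig) -> SimulatedDataset:
    """Draw a complete two-population diploid dataset from the config.

    The same seed reproduces byte-identical output: all randomness flows
    through one ``numpy`` Generator in a fixed iteration order (loci, then
    sites, then haplotypes).
    """
    rng = np.random.default_rng(cfg.seed)
    loci = {l.locus_id: l for l in cfg.loci}
    for s in cfg.selected_sites:
        if s.locus_id not in loci:
            raise ValueError(f"selected site references unknown locus {s.locus_id}")
        if not 0 <= s.column < loci[s.locus_id].length:
            raise ValueError(f"selected site column {s.column} outside locus "
                             f"{s.locus_id}")
    blocks = _assign_blocks(cfg, loci)
    block_of = {id(s): bi for bi, block in enumerate(blocks) for s in block}

    # Per-locus scaffolding: reference sequence, site columns, frequencies.
    ref: dict[str, np.ndarray] = {}
    neutral_cols: dict[str, np.ndarray] = {}
    neutral_freq: dict[str, np.ndarray] = {}
    sel_by_locus = {lid: [] for lid in loci}
    for s in cfg.selected_sites:
        sel_by_locus[s.locus_id].append(s)
    lo, hi = cfg.background_freq
    for spec in cfg.loci:
        ref[spec.locus_id] = rng.choice(BASES, size=spec.length)
        taken = {s.column for s in sel_by_locus[spec.locus_id]}
        free = np.array(sorted(set(range(spec.length)) - taken))
        cols = np.sort(rng.choice(free, size=spec.n_neutral_sites, replace=False))
        neutral_cols[spec.locus_id] = cols
        neutral_freq[spec.locus_id] = rng.uniform(lo, hi, size=spec.n_neutral_sites)

    # Haplotype plan: pure A, pure B, then one A-process + one B-process
    # haplotype per admixed individual.
    hap_pops = (
        ["A"] * (2 * cfg.n_per_pop)
        + ["B"] * (2 * cfg.n_per_pop)
        + ["A", "B"] * cfg.n_admixed
    )
    n_haps = len(hap_pops)

    # Draw derived/ancestral states per site for all haplotypes.
    states: dict[str, np.ndarray] = {
        lid: np.zeros((n_haps, loci[lid].length), dtype=bool) for lid in loci
    }
    block_u = rng.random((n_haps, len(blocks)))  # one shared uniform per block
    for spec in cfg.loci:
        lid = spec.locus_id
        for col, p in zip(neutral_cols[lid], neutral_freq[lid]):
            draws = rng.random(n_haps) < p  # shared frequency in both pops
            states[lid][:, col] = draws
        for s in sel_by_locus[lid]:
            u = block_u[:, block_of[id(s)]]
            p_vec = np.where(np.array(hap_pops) == "A", s.p_a, s.p_b)
            states[lid][:, s.column] = u < p_vec

    # Missingness at variant columns.
    missing: dict[str, np.ndarray] = {}
    for spec in cfg.loci:
        lid = spec.locus_id
        var_cols = np.concatenate(
            [neutral_cols[lid], [s.column for s in sel_by_locus[lid]]]
        ).astype(int)
        mask = np.zeros((n_haps, spec.length), dtype=bool)
        if cfg.missing_rate > 0:
            mask[:, var_cols] = rng.random((n_haps, len(var_cols))) < cfg.missing_rate
        missing[lid] = mask

    # Individuals and haplotype names.
    samples: list[SampleRecord] = []
    hap_names: list[str] = []

    def _add(ind_id: str, population: str, score: float) -> None:
        names = (f"{ind_id}_a", f"{ind_id}_b")
        hap_names.extend(names)
        samples.append(SampleRecord(ind_id, population, cfg.comparison, score, names))

    for i in range(cfg.n_per_pop):
        _add(f"{cfg.pop_a}_{i + 1:02d}", cfg.pop_a, 0.0)
    for i in range(cfg.n_per_pop):
        _add(f"{cfg.pop_b}_{i + 1:02d}", cfg.pop_b, 1.0)
    for i in range(cfg.n_admixed):
        # Housed in the B-race sample, as admixed field specimens were.
        _add(f"admixed_{i + 1:02d}", cfg.pop_b, 0.5)

    alignments = []
    next_base = {b: BASES[(i + 1) % 4] for i, b in enumerate(BASES)}
    for spec in cfg.loci:
        lid = spec.locus_id
        derived = np.array([next_base[b] for b in ref[lid]])
        seqs = []
        for h, name in enumerate(hap_names):
            chars = np.where(states[lid][h], derived, ref[lid])
            chars = np.where(missing[lid][h], "N", chars)
            seqs.append((name, "".join(chars)))
        alignments.append(LocusAlignment(lid, spec.region, spec.offset, seqs))

    locus_meta = {
        l.locus_id: LocusMeta(l.locus_id, l.region, l.offset) for l in cfg.loci
    }
    selected_positions = [
        (s.locus_id, s.column + 1) if loci[s.locus_id].offset is None
        else (s.locus_id, loci[s.locus_id].offset + s.column + 1)
        for s in cfg.selected_sites
    ]
    block_positions = [
        [
            (s.locus_id, s.column + 1) if loci[s.locus_id].offset is None
            else (s.locus_id, loci[s.locus_id].offset + s.column + 1)
            for s in block
        ]
        for block in blocks
    ]
    return SimulatedDataset(alignments, samples, locus_meta,
                            selected_positions, block_positions)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Emit FASTA per locus plus samples.tsv and loci.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for aln in ds.alignments:
        write_fasta(aln, out / f"{aln.locus_id}.fasta")
    with open(out / "samples.tsv", "w") as fh:
        fh.write("individual_id\tpopulation\tcomparison\tphenotype_score\thap1\thap2\n")
        for s in ds.samples:
            score = "NA" if s.phenotype_score is None else f"{s.phenotype_score:.1f}"
            fh.write(f"{s.individual_id}\t{s.population}\t{s.comparison}\t"
                     f"{score}\t{s.haplotype_names[0]}\t{s.haplotype_names[1]}\n")
    with open(out / "loci.tsv", "w") as fh:
        fh.write("locus_id\tregion\tgenomic_offset\tnotes\n")
        for m in ds.locus_meta.values():
            off = "" if m.genomic_offset is None else str(m.genomic_offset)
            fh.write(f"{m.locus_id}\t{m.region}\t{off}\t{m.notes}\n")


def simulate_coalescent_sample(
    n: int, theta: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Neutral coalescent haplotypes without recombination, infinite sites.

    Coalescence times are exponential with rate C(k, 2); mutations fall on
    each branch as Poisson(theta/2 * branch length), each creating one new
    segregating column carried by the leaves the branch subtends. Returns an
    (n, S) 0/1 matrix (ancestral/derived); S may be 0.
    """
    if n < 2:
        raise ValueError("coalescent sample needs n >= 2")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lineages: list[tuple[tuple[int, ...], float]] = [((i,), 0.0) for i in range(n)]
    branches: list[tuple[tuple[int, ...], float]] = []
    while len(lineages) > 1:
        k = len(lineages)
        dt = rng.exponential(2.0 / (k * (k - 1)))
        lineages = [(leaves, length + dt) for leaves, length in lineages]
        i, j = sorted(rng.choice(k, size=2, replace=False))
        leaves_j, len_j = lineages.pop(j)
        leaves_i, len_i = lineages.pop(i)
        branches.append((leaves_i, len_i))
        branches.append((leaves_j, len_j))
        lineages.append((tuple(sorted(leaves_i + leaves_j)), 0.0))
    columns = []
    for leaves, length in branches:
        if len(leaves) == n:
            continue  # subtends the whole sample: not segregating
        m = rng.poisson(theta / 2 * length)
        for _ in range(m):
            col = np.zeros(n, dtype=np.int8)
            col[list(leaves)] = 1
            columns.append(col)
    if not columns:
        return np.zeros((n, 0), dtype=np.int8)
    return np.column_stack(columns)


def haplotype_matrix_stats(matrix: np.ndarray) -> tuple[int, int, float]:
    """(n, S, mean pairwise differences) of a 0/1 haplotype matrix."""
    n, S = matrix.shape
    if S == 0:
        return n, 0, 0.0
    k = matrix.sum(axis=0)
    pi_total = float((2 * k * (n - k) / (n * (n - 1))).sum())
    return n, S, pi_total


def simulate_ct_table(
    seed: int | np.random.Generator,
    genes: Sequence[str] = ("kinesin",),
    race_fold: float = 2.6,
    n_individuals: int = 3,
    noise_sd: float = 0.25,
    reference_ct: float = 20.0,
) -> "pd.DataFrame":
    """Synthetic qPCR Ct table for the between-races experiment design.

    24 samples per gene (individuals x {forewing, hindwing} x {L5, EP} x
    two races); the first gene carries a ``race_fold`` expression ratio
    (race m over race c), plus a mild stage effect; remaining genes are
    race-independent. Returns the columns ``read_ct_table`` expects.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for gene_idx, gene in enumerate(genes):
        for race in ("m", "c"):
            for stage in ("L5", "EP"):
                for wing in ("F", "H"):
                    for ind in range(1, n_individuals + 1):
                        log2_expr = (
                            1.0
                            + (math.log2(race_fold) if race == "m" and gene_idx == 0
                               else 0.0)
                            + (0.4 if stage == "EP" else 0.0)
                            + rng.normal(0, noise_sd)
                        )
                        ct_ref = reference_ct + rng.normal(0, 0.3)
                        rows.append({
                            "sample_id": f"{race}_{stage}_{wing}_{ind}",
                            "gene": gene,
                            "ct_target": ct_ref - log2_expr,
                            "ct_reference": ct_ref,
                            "race": race, "stage": stage, "wing": wing,
                        })
    return pd.DataFrame(rows)


def expected_hudson_fst(
    p_a: float, p_b: float, n_a: int | None = None, n_b: int | None = None
) -> float:
    """Closed-form single-site Hudson FST from population frequencies.

    Sample within/between mean pairwise differences are unbiased for
    pa*qa + pb*qb and pa(1-pb) + pb(1-pa) respectively, so the expected-
    component plug-in does not depend on the sample sizes (kept in the
    signature for clarity); the estimator's ratio bias is O(1/n).
    NaN when the between-population expectation is zero.
    """
    for p in (p_a, p_b):
        if not 0 <= p <= 1:
            raise ValueError(f"frequency {p} outside [0, 1]")
    Hw = p_a * (1 - p_a) + p_b * (1 - p_b)
    Hb = p_a * (1 - p_b) + p_b * (1 - p_a)
    if Hb == 0:
        return math.nan
    return 1 - Hw / Hb
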