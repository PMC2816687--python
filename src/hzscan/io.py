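"""Readers and writers for the pipeline's file formats.

Alignments arrive as per-locus FASTA files (two haplotype sequences per
diploid individual), sample metadata and locus metadata as TSV tables.
All results leave as TSV. Coordinates are 0-based internally and 1-based
in every written file; the global position of an alignment column is
``genomic_offset + column`` (1-based).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("hzscan")

REGIONS = ("HmYb", "HmB", "unlinked")
VALID_SCORES = (0.0, 0.5, 1.0)
_AMBIGUITY = set("RYSWKMBDHVU")


@dataclass
class LocusAlignment:
    """A multiple sequence alignment of population haplotypes for one locus.

    ``region`` marks whether the locus sits in one of the two colour-pattern
    candidate regions (HmYb, HmB) or is an unlinked control; ``genomic_offset``
    places alignment column 1 on a shared coordinate axis (``None`` when the
    locus has no placement, e.g. unlinked controls).
    """

    locus_id: str
    region: str = "unlinked"
    genomic_offset: int | None = None
    sequences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(
                f"locus {self.locus_id}: unknown region {self.region!r}; "
                f"expected one of {REGIONS}"
            )
        if len(self.sequences) < 2:
            raise ValueError(f"locus {self.locus_id}: needs >=2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"locus {self.locus_id}: ragged alignment (lengths {sorted(lengths)})"
            )
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise ValueError(f"locus {self.locus_id}: duplicate sequence names")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    def subset(self, names: Sequence[str]) -> "LocusAlignment":
        """Restrict to the named haplotypes (order follows ``names``)."""
        by_name = dict(self.sequences)
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"locus {self.locus_id}: haplotypes not found: {missing}")
        return LocusAlignment(
            self.locus_id, self.region, self.genomic_offset,
            [(n, by_name[n]) for n in names],
        )

    def global_position(self, column: int) -> int | None:
        """1-based position of a 0-based alignment column on the shared axis."""
        if self.genomic_offset is None:
            return None
        return self.genomic_offset + column + 1


@dataclass
class SampleRecord:
    """One diploid individual: population labels, phenotype score, haplotypes.

    ``phenotype_score`` follows the 0.0 / 0.5 / 1.0 coding of colour-pattern
    genotype (alternative homozygotes and heterozygote); ``None`` is missing.
    """

    individual_id: str
    population: str
    comparison: str
    phenotype_score: float | None
    haplotype_names: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.haplotype_names) != 2:
            raise ValueError(
                f"individual {self.individual_id}: exactly two haplotypes required"
            )
        s = self.phenotype_score
        if s is not None and s not in VALID_SCORES:
            raise ValueError(
                f"individual {self.individual_id}: invalid phenotype score {s!r} "
                f"(allowed: 0, 0.5, 1, NA)"
            )


@dataclass
class LocusMeta:
    locus_id: str
    region: str = "unlinked"
    genomic_offset: int | None = None
    notes: str = ""


def _clean_sequence(seq: str, path: str) -> str:
    """Uppercase; collapse IUPAC ambiguity codes to N; keep A/C/G/T/N/-."""
    out = []
    for ch in seq.upper():
        if ch in "ACGTN-":
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
        else:
            raise ValueError(f"{path}: unexpected character {ch!r} in sequence")
    return "".join(out)


def read_locus_alignments(
    paths: Iterable[str | Path],
    locus_meta: Mapping[str, LocusMeta] | None = None,
) -> list[LocusAlignment]:
    """Read one FASTA alignment per path; join region/offset from metadata.

    The locus id is the file stem. Loci absent from ``locus_meta`` fall back
    to region ``unlinked`` with no genomic offset (warning logged). Ragged or
    empty alignments are hard errors naming the file.
    """
    locus_meta = locus_meta or {}
    alignments = []
    for path in paths:
        path = Path(path)
        locus_id = path.stem
        records = [
            (rec.id, _clean_sequence(str(rec.seq), str(path)))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not records:
            raise ValueError(f"{path}: empty FASTA file")
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            raise ValueError(f"{path}: ragged alignment (lengths {sorted(lengths)})")
        meta = locus_meta.get(locus_id)
        if meta is None:
            if locus_meta:
                logger.warning(
                    "locus %s not in locus metadata; using region=unlinked, no offset",
                    locus_id,
                )
            meta = LocusMeta(locus_id)
        alignments.append(
            LocusAlignment(locus_id, meta.region, meta.genomic_offset, records)
        )
    return alignments


def read_locus_table(path: str | Path) -> dict[str, LocusMeta]:
    """Read locus metadata TSV (locus_id, region, genomic_offset[, notes])."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    required = {"locus_id", "region"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: locus table needs columns {sorted(required)}")
    if df["locus_id"].duplicated().any():
        dups = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
        raise ValueError(f"{path}: duplicated locus ids {dups}")
    meta = {}
    for row in df.itertuples(index=False):
        offset = getattr(row, "genomic_offset", None)
        if offset is None or (isinstance(offset, float) and math.isnan(offset)):
            offset = None
        else:
            offset = int(offset)
        meta[row.locus_id] = LocusMeta(
            row.locus_id, row.region, offset, str(getattr(row, "notes", "") or "")
        )
    return meta


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the sample TSV.

    Required columns: individual_id, population, comparison, phenotype_score
    (``NA`` allowed). Haplotype columns hap1/hap2 are optional; when absent,
    pairs are inferred as ``<individual_id>_a`` / ``<individual_id>_b``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "population", "comparison", "phenotype_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        raw = row.phenotype_score
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "NA":
            score = None
        else:
            score = float(raw)
            if score not in VALID_SCORES:
                raise ValueError(
                    f"{path}: invalid phenotype score {raw!r} for "
                    f"{row.individual_id} (allowed: 0, 0.5, 1, NA)"
                )
        if "hap1" in df.columns and "hap2" in df.columns:
            haps = (row.hap1, row.hap2)
        else:
            haps = (f"{row.individual_id}_a", f"{row.individual_id}_b")
        records.append(
            SampleRecord(row.individual_id, row.population, row.comparison, score, haps)
        )
    seen: dict[str, str] = {}
    for rec in records:
        for hap in rec.haplotype_names:
            if hap in seen:
                raise ValueError(
                    f"{path}: haplotype {hap!r} assigned twice "
                    f"({seen[hap]} and {rec.individual_id})"
                )
            seen[hap] = rec.individual_id
    return records


def match_samples_to_alignment(
    samples: Sequence[SampleRecord], aln: LocusAlignment
) -> tuple[list[SampleRecord], int]:
    """Samples whose two haplotypes are both present in the alignment.

    Individuals missing one or both haplotypes at this locus are excluded
    (returned count), mirroring per-locus exclusion of sequencing failures.
    """
    present = set(aln.names)
    kept, excluded = [], 0
    for rec in samples:
        if all(h in present for h in rec.haplotype_names):
            kept.append(rec)
        else:
            excluded += 1
    if excluded:
        logger.warning(
            "locus %s: excluded %d individual(s) without both haplotypes",
            aln.locus_id, excluded,
        )
    return kept, excluded


def write_results_table(records: Sequence, path: str | Path) -> None:
    """Write homogeneous result records (dataclasses or dicts) as TSV.

    Column order follows the record's field order; floats are written at six
    significant digits; an empty list yields a header-only file when the
    record type is known, otherwise an empty file with a comment header.
    """
    path = Path(path)
    if records and dataclasses.is_dataclass(records[0]):
        columns = [f.name for f in dataclasses.fields(records[0])]
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=columns)
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def write_fasta(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
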