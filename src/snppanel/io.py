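"""Shared I/O: FASTA references, BED repeat intervals, call tables, panel VCF.

Coordinate conventions are fixed package-wide: FASTA and VCF positions are
1-based inclusive; BED intervals are 0-based half-open.  Malformed lines are
rejected with the file name and line number in the error message.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A file did not conform to its declared format."""


@dataclasses.dataclass
class ReferenceSet:
    """Named scaffolds plus their repeat annotation.

    ``sequences`` maps scaffold name to an upper-case nucleotide string.
    ``repeats`` maps scaffold name to 0-based half-open ``(start, end)``
    intervals annotated as repetitive (exact repeat copies and planted
    homopolymer runs, for simulated references).
    """

    sequences: dict[str, str]
    repeats: dict[str, list[tuple[int, int]]] = dataclasses.field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self.sequences.values())

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        """Return the 0-based half-open slice ``[start, end)`` of a scaffold."""
        return self.sequences[scaffold][start:end]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> ReferenceSet:
    """Load scaffolds from a FASTA file (no repeat annotation)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"{path}: duplicate scaffold name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return ReferenceSet(sequences=sequences)


def write_fasta(ref: ReferenceSet, path: str | Path, width: int = 60) -> None:
    """Write scaffolds as FASTA with fixed-width line wrapping."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in ref.sequences.items()
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read 0-based half-open intervals from a 3+ column BED file."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.setdefault(fields[0], []).append((start, end))
    return intervals


def write_bed(intervals: Mapping[str, Iterable[tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold in sorted(intervals):
            for start, end in sorted(intervals[scaffold]):
                fh.write(f"{scaffold}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Pileup / call tables (TSV)

PILEUP_COLUMNS = [
    "scaffold", "pos", "ref_base", "depth",
    "ref_count", "alt_base", "alt_count", "other_count", "gap_count",
]

CALL_COLUMNS = ["scaffold", "pos", "ref", "alt", "genotype", "Q", "depth", "gap_count"]


def write_pileup(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "alt_base": str})
    missing = set(PILEUP_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing pileup columns {sorted(missing)}")
    table["alt_base"] = table["alt_base"].fillna(".")
    return table


def write_calls(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=CALL_COLUMNS)


def read_calls(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "alt": str})
    missing = set(CALL_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing call columns {sorted(missing)}")
    table["alt"] = table["alt"].fillna(".")
    return table


def read_scaffold_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column scaffold-length TSV (name, length in nt)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                lengths[fields[0]] = int(fields[1].replace(",", ""))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
    return lengths


# ---------------------------------------------------------------------------
# Panel VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=snppanel
##INFO=<ID=INFP,Number=1,Type=String,Description="Informative (heterozygous) parent">
##INFO=<ID=MINDP,Number=1,Type=Integer,Description="Minimum per-parent depth at site">
{filters}{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    panel: pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    filter_names: Iterable[str] = (),
) -> None:
    """Write candidates as a minimal VCF.

    ``panel`` needs columns scaffold, pos (1-based), ref, alt, Q, filter
    (first failing filter name or "PASS"), informative_parent, min_parent_depth.
    Rows are emitted in (scaffold, pos) order.
    """
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={name},length={length}>\n"
            for name, length in contig_lengths.items()
        )
    filters = "".join(
        f'##FILTER=<ID={name},Description="Failed {name} filter">\n'
        for name in filter_names
    )
    ordered = panel.sort_values(["scaffold", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contigs, filters=filters))
        for row in ordered.itertuples(index=False):
            parent = getattr(row, "informative_parent", None)
            info_parts = []
            if parent and parent != ".":
                info_parts.append(f"INFP={parent}")
            min_dp = getattr(row, "min_parent_depth", None)
            if min_dp is not None and not pd.isna(min_dp):
                info_parts.append(f"MINDP={int(min_dp)}")
            info = ";".join(info_parts) or "."
            fh.write(
                f"{row.scaffold}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.Q:.2f}\t{row.filter}\t{info}\n"
            )


SAMPLE_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=snppanel
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tFORMAT\t{sample}
"""

_GT_CODE = {"hom-ref": "0/0", "het": "0/1", "hom-alt": "1/1", "no-call": "./."}


def write_single_sample_vcf(
    calls: pd.DataFrame,
    sample: str,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    variant_only: bool = True,
) -> None:
    """Write one parent's calls as a minimal single-sample VCF (QUAL = Q)."""
    contigs = ""
    if contig_lengths:
        contigs = "".join(
            f"##contig=<ID={name},length={length}>\n"
            for name, length in contig_lengths.items()
        )
    table = calls
    if variant_only:
        table = table[table["genotype"].isin(("het", "hom-alt"))]
    ordered = table.sort_values(["scaffold", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(SAMPLE_VCF_HEADER.format(contigs=contigs, sample=sample))
        for row in ordered.itertuples(index=False):
            alt = row.alt if row.alt != "." else "."
            fh.write(
                f"{row.scaffold}\t{int(row.pos)}\t.\t{row.ref}\t{alt}\t"
                f"{row.Q:.2f}\t.\tGT\t{_GT_CODE[row.genotype]}\n"
            )


def read_vcf_panel(path: str | Path, pass_only: bool = True) -> pd.DataFrame:
    """Read a panel VCF back into a candidate table (1-based positions)."""
    from cyvcf2 import VCF

    rows = []
    for variant in VCF(str(path)):
        status = variant.FILTER or "PASS"  # cyvcf2 reports PASS as None
        if pass_only and status != "PASS":
            continue
        rows.append(
            {
                "scaffold": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0] if variant.ALT else ".",
                "Q": float(variant.QUAL) if variant.QUAL is not None else 0.0,
                "filter": status,
                "informative_parent": variant.INFO.get("INFP", "."),
                "min_parent_depth": variant.INFO.get("MINDP", 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "pos", "ref", "alt", "Q",
            "filter", "informative_parent", "min_parent_depth",
        ],
    )
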