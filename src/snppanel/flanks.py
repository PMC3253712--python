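"""Assay flank extraction and a k-mer uniqueness screen.

Genotyping-assay probes need the exact sequence context of each marker:
60 bases on either side of the SNP, 121 bases in total, written in the
bracketed GoldenGate convention ``LEFT[REF/ALT]RIGHT``.  Candidates closer
than 60 bases to a scaffold end are dropped (flag ``edge``) — probes need
full context and padding would fabricate sequence.

Markers whose context is not unique in the reference make unreliable probes.
The screen here asks whether every k-mer window (default k = 31) of the
121-base context occurs exactly once in the reference, counting both strands
via canonical k-mers; any N in the context disqualifies it outright.  This is
a deterministic, exhaustively checkable criterion that flags exactly the
contexts lying in or overlapping repeated sequence.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import ReferenceSet

HALF_WINDOW = 60
DEFAULT_K = 31

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class EdgeError(ValueError):
    """Candidate lies too close to a scaffold end for a full flank."""


class DuplicateIdError(ValueError):
    """Two flank records share an snp_id."""


@dataclasses.dataclass
class FlankRecord:
    """The 121-base assay context of one SNP."""

    snp_id: str
    scaffold: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    upstream: str
    downstream: str
    unique: bool | None = None

    def __post_init__(self) -> None:
        half = len(self.upstream)
        if len(self.downstream) != half:
            raise ValueError("upstream and downstream flank lengths differ")

    @property
    def context(self) -> str:
        """The plain 121-base reference context (ref allele at the centre)."""
        return self.upstream + self.ref_allele + self.downstream

    @property
    def assay_string(self) -> str:
        """Bracketed probe-design string LEFT[REF/ALT]RIGHT."""
        return f"{self.upstream}[{self.ref_allele}/{self.alt_allele}]{self.downstream}"


def snp_id(scaffold: str, position: int, ref: str, alt: str) -> str:
    return f"{scaffold}:{position}:{ref}:{alt}"


def parse_snp_id(identifier: str) -> tuple[str, int, str, str]:
    scaffold, pos, ref, alt = identifier.rsplit(":", 3)
    return scaffold, int(pos), ref, alt


def extract_flank(
    ref: ReferenceSet,
    scaffold: str,
    position: int,
    ref_allele: str | None = None,
    alt_allele: str = ".",
    half_window: int = HALF_WINDOW,
) -> FlankRecord:
    """Cut the half_window/SNP/half_window context from the reference.

    Raises EdgeError when fewer than ``half_window`` bases exist on either
    side; batch callers turn that into an ``edge`` drop flag.
    """
    seq = ref.sequences[scaffold]
    if position < half_window + 1 or position > len(seq) - half_window:
        raise EdgeError(
            f"{scaffold}:{position} is within {half_window} bases of a scaffold end"
        )
    centre = seq[position - 1]
    if ref_allele is not None and ref_allele != centre:
        raise ValueError(
            f"reference allele mismatch at {scaffold}:{position}: "
            f"expected {ref_allele}, reference has {centre}"
        )
    return FlankRecord(
        snp_id=snp_id(scaffold, position, centre, alt_allele),
        scaffold=scaffold,
        position=position,
        ref_allele=centre,
        alt_allele=alt_allele,
        upstream=seq[position - 1 - half_window : position - 1],
        downstream=seq[position : position + half_window],
    )


def extract_flanks(
    ref: ReferenceSet, panel: pd.DataFrame, half_window: int = HALF_WINDOW
) -> tuple[list[FlankRecord], pd.DataFrame]:
    """Extract flanks for a whole panel; edge candidates go to the drop table."""
    records: list[FlankRecord] = []
    dropped = []
    for row in panel.itertuples(index=False):
        try:
            records.append(
                extract_flank(
                    ref, str(row.scaffold), int(row.pos),
                    ref_allele=str(row.ref), alt_allele=str(row.alt),
                    half_window=half_window,
                )
            )
        except EdgeError:
            dropped.append({"scaffold": row.scaffold, "pos": row.pos, "flag": "edge"})
    return records, pd.DataFrame(dropped, columns=["scaffold", "pos", "flag"])


# ---------------------------------------------------------------------------
# Uniqueness

def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


class KmerIndex:
    """Counts of canonical k-mers across a reference (both strands).

    A forward k-mer and its reverse complement are the same probe-binding
    site, so occurrences are counted on the canonical representative.
    """

    def __init__(self, ref: ReferenceSet, k: int = DEFAULT_K) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        counts: Counter[str] = Counter()
        for seq in ref.sequences.values():
            for i in range(len(seq) - k + 1):
                counts[_canonical(seq[i : i + k])] += 1
        self._counts = counts

    def count(self, kmer: str) -> int:
        return self._counts[_canonical(kmer)]

    def max_multiplicity(self, sequence: str) -> int:
        """Highest reference count over all k-mer windows of ``sequence``."""
        k = self.k
        if len(sequence) < k:
            raise ValueError(f"sequence shorter than k={k}")
        return max(self.count(sequence[i : i + k]) for i in range(len(sequence) - k + 1))


def uniqueness_screen(
    flank: FlankRecord,
    ref: ReferenceSet | KmerIndex,
    k: int = DEFAULT_K,
) -> bool:
    """True iff every k-mer of the context occurs exactly once in the reference.

    Accepts a prebuilt KmerIndex to amortise the reference scan over a panel.
    Contexts containing N are never unique.
    """
    context = flank.context
    if k > len(context):
        raise ValueError(f"k={k} exceeds context length {len(context)}")
    if "N" in context:
        return False
    index = ref if isinstance(ref, KmerIndex) else KmerIndex(ref, k)
    if index.k != k:
        raise ValueError(f"index built with k={index.k}, screen requested k={k}")
    return index.max_multiplicity(context) == 1


def screen_flanks(
    flanks: list[FlankRecord], ref: ReferenceSet, k: int = DEFAULT_K
) -> list[FlankRecord]:
    """Set the ``unique`` flag on every record using one shared index."""
    index = KmerIndex(ref, k)
    for record in flanks:
        record.unique = uniqueness_screen(record, index, k)
    return flanks


# ---------------------------------------------------------------------------
# Export

_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("CG"): "S", frozenset("AT"): "W",
}


def _sorted_unique(flanks: Iterable[FlankRecord]) -> list[FlankRecord]:
    records = sorted(flanks, key=lambda r: (r.scaffold, r.position))
    seen: set[str] = set()
    for record in records:
        if record.snp_id in seen:
            raise DuplicateIdError(f"duplicate snp_id {record.snp_id}")
        seen.add(record.snp_id)
        if record.unique is False:
            raise ValueError(
                f"{record.snp_id} failed the uniqueness screen; export unique records only"
            )
    return records


def export_assay_fasta(flanks: Iterable[FlankRecord], path: str | Path) -> int:
    """Write bracketed assay strings as FASTA, ordered by (scaffold, position).

    Returns the number of records written.  Every body is 125 characters:
    119 flanking bases around a five-character "[R/A]" allele block.
    """
    records = _sorted_unique(flanks)
    seq_records = [
        SeqRecord(Seq(r.assay_string), id=r.snp_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    return len(records)


def export_consensus_fasta(flanks: Iterable[FlankRecord], path: str | Path) -> int:
    """Write plain 121-base contexts with an IUPAC ambiguity code at the centre."""
    records = _sorted_unique(flanks)
    seq_records = []
    for r in records:
        code = _IUPAC.get(frozenset((r.ref_allele, r.alt_allele)), "N")
        seq_records.append(
            SeqRecord(Seq(r.upstream + code + r.downstream), id=r.snp_id, description="")
        )
    SeqIO.write(seq_records, str(path), "fasta")
    return len(records)


def read_assay_fasta(path: str | Path) -> list[FlankRecord]:
    """Parse an exported assay FASTA back into flank records."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        scaffold, position, ref_allele, alt_allele = parse_snp_id(entry.id)
        body = str(entry.seq)
        left, rest = body.split("[", 1)
        alleles, right = rest.split("]", 1)
        ref_b, alt_b = alleles.split("/")
        if (ref_b, alt_b) != (ref_allele, alt_allele):
            raise ValueError(f"{entry.id}: body alleles disagree with id")
        records.append(
            FlankRecord(
                snp_id=entry.id, scaffold=scaffold, position=position,
                ref_allele=ref_allele, alt_allele=alt_allele,
                upstream=left, downstream=right, unique=True,
            )
        )
    return records


def flank_table(flanks: Iterable[FlankRecord]) -> pd.DataFrame:
    rows = [
        {
            "snp_id": r.snp_id, "scaffold": r.scaffold, "pos": r.position,
            "unique": r.unique, "context": r.context,
        }
        for r in sorted(flanks, key=lambda r: (r.scaffold, r.position))
    ]
    return pd.DataFrame(rows, columns=["snp_id", "scaffold", "pos", "unique", "context"])
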