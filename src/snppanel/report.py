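"""Per-scaffold, quality-stratified marker-density reporting.

For each scaffold the report counts panel SNPs with quality strictly above
two phred thresholds (defaults Q1 = 100, Q2 = 200) and expresses density as
scaffold length per SNP, rounded half-away-from-zero to whole nucleotides —
"one SNP every N bases".  Genome-level coverage is summarised as the mean of
the per-scaffold ratios over the *major* scaffolds (by default the eight
longest, the chromosome-scale sequences); small leftover scaffolds with a
handful of markers would otherwise dominate a naive mean, and the ratio of
totals would hide how uneven coverage is between chromosomes.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NA = "na"

REPORT_COLUMNS = [
    "scaffold", "n_snps_q1", "n_snps_q2", "length_nt",
    "length_per_snp_q1", "length_per_snp_q2",
]


class MissingLengthError(KeyError):
    """A panel scaffold has no entry in the length table."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclasses.dataclass
class DensityReport:
    """Per-scaffold SNP counts and length-per-SNP ratios at two Q strata."""

    rows: pd.DataFrame  # REPORT_COLUMNS; ratio columns hold int or the string "na"
    q1: float
    q2: float
    major_scaffolds: list[str]

    @property
    def total_snps_q1(self) -> int:
        return int(self.rows["n_snps_q1"].sum())

    @property
    def total_snps_q2(self) -> int:
        return int(self.rows["n_snps_q2"].sum())

    @property
    def total_length(self) -> int:
        return int(self.rows["length_nt"].sum())

    def _major_ratios(self, column: str) -> list[int]:
        major = self.rows[self.rows["scaffold"].isin(self.major_scaffolds)]
        return [r for r in major[column] if r != NA]

    def mean_ratio(self, stratum: int = 1) -> int | str:
        """Mean of per-major-scaffold ratios, rounded to whole nucleotides."""
        ratios = self._major_ratios(f"length_per_snp_q{stratum}")
        if not ratios:
            return NA
        return round_half_away(float(np.mean(ratios)))

    def ratio_spread(self, stratum: int = 1) -> tuple[float, float, int]:
        """(mean, sample SD, CV%) of the per-major-scaffold ratios."""
        ratios = self._major_ratios(f"length_per_snp_q{stratum}")
        if len(ratios) < 2:
            return (float(ratios[0]) if ratios else float("nan"), 0.0, 0)
        mean = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1))
        cv = round_half_away(100.0 * sd / mean) if mean else 0
        return mean, sd, cv


def _ratio(length: int, count: int) -> int | str:
    return NA if count == 0 else round_half_away(length / count)


def select_major_scaffolds(
    scaffold_lengths: Mapping[str, int], n_major: int = 8
) -> list[str]:
    """The n longest scaffolds (ties broken by name for determinism)."""
    ranked = sorted(scaffold_lengths.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:n_major]]


def density_report_from_counts(
    counts: pd.DataFrame,
    q1: float = 100.0,
    q2: float = 200.0,
    major_scaffolds: Sequence[str] | None = None,
    n_major: int = 8,
) -> DensityReport:
    """Build the report from precomputed per-scaffold counts.

    ``counts`` needs columns scaffold, n_snps_q1, n_snps_q2, length_nt — the
    shape of a published per-scaffold marker table, so printed tables can be
    fed straight back through the density arithmetic.
    """
    rows = counts[["scaffold", "n_snps_q1", "n_snps_q2", "length_nt"]].copy()
    rows["length_per_snp_q1"] = [
        _ratio(l, c) for l, c in zip(rows["length_nt"], rows["n_snps_q1"])
    ]
    rows["length_per_snp_q2"] = [
        _ratio(l, c) for l, c in zip(rows["length_nt"], rows["n_snps_q2"])
    ]
    if major_scaffolds is None:
        lengths = dict(zip(rows["scaffold"], rows["length_nt"]))
        major_scaffolds = select_major_scaffolds(lengths, n_major)
    return DensityReport(
        rows=rows.reset_index(drop=True), q1=q1, q2=q2,
        major_scaffolds=list(major_scaffolds),
    )


def density_report(
    panel: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    q1: float = 100.0,
    q2: float = 200.0,
    major_scaffolds: Sequence[str] | None = None,
    n_major: int = 8,
) -> DensityReport:
    """Count panel SNPs above each quality stratum per scaffold.

    ``panel`` needs scaffold and Q columns (one row per retained SNP); both
    stratum counts use strict inequality Q > threshold.  Scaffolds present in
    the length table but absent from the panel get zero counts; a panel
    scaffold missing from the length table is an error naming the scaffold.
    """
    missing = set(panel["scaffold"].unique()) - set(scaffold_lengths)
    if missing:
        raise MissingLengthError(
            f"no length entry for scaffold(s): {', '.join(sorted(str(m) for m in missing))}"
        )
    rows = []
    for scaffold, length in scaffold_lengths.items():
        quals = panel.loc[panel["scaffold"] == scaffold, "Q"]
        rows.append(
            {
                "scaffold": scaffold,
                "n_snps_q1": int((quals > q1).sum()),
                "n_snps_q2": int((quals > q2).sum()),
                "length_nt": int(length),
            }
        )
    return density_report_from_counts(
        pd.DataFrame(rows), q1=q1, q2=q2,
        major_scaffolds=major_scaffolds, n_major=n_major,
    )


def panel_summary(report: DensityReport) -> dict:
    """Whole-panel summary: totals plus spread of the major-scaffold ratios."""
    mean1, sd1, cv1 = report.ratio_spread(1)
    mean2, sd2, cv2 = report.ratio_spread(2)
    return {
        "total_snps_q1": report.total_snps_q1,
        "total_snps_q2": report.total_snps_q2,
        "total_length": report.total_length,
        "mean_ratio_q1": report.mean_ratio(1),
        "mean_ratio_q2": report.mean_ratio(2),
        "sd_ratio_q1": sd1,
        "sd_ratio_q2": sd2,
        "cv_percent_q1": cv1,
        "cv_percent_q2": cv2,
    }


def write_report_tsv(report: DensityReport, path: str | Path) -> None:
    """Write per-scaffold rows plus a Total row; byte-deterministic."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in report.rows.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\t{row.n_snps_q1}\t{row.n_snps_q2}\t{row.length_nt}\t"
                f"{row.length_per_snp_q1}\t{row.length_per_snp_q2}\n"
            )
        fh.write(
            f"Total\t{report.total_snps_q1}\t{report.total_snps_q2}\t"
            f"{report.total_length}\tave. = {report.mean_ratio(1)}\t"
            f"ave. = {report.mean_ratio(2)}\n"
        )


def load_example_counts() -> pd.DataFrame:
    """Bundled example: per-scaffold SNP counts and lengths for a peach panel.

    Twenty scaffolds of the peach reference assembly with counts of mapping
    markers above Q 100 and Q 200 — a ready-made input for
    :func:`density_report_from_counts` (the eight chromosome-scale scaffolds
    are the majors).
    """
    path = resources.files("snppanel").joinpath("data/peach_scaffold_counts.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
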