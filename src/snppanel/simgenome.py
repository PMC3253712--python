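"""Synthetic diploid cross simulator: reference scaffolds, parental truth
sets, and noisy per-site pileup evidence.

The simulator emulates the inputs of a marker-discovery experiment in a
biparental cross: a set of reference scaffolds with planted exact repeats and
homopolymer runs, diploid genotypes for each parent at spiked variant sites,
and per-parent allele-count pileups with Poisson sequencing depth and a
symmetric per-read miscall probability.  Everything is driven by one integer
seed; per-purpose random streams are derived from it so that, for example,
adding a parent does not perturb the reference or the other parents' reads.

Informative sites — heterozygous in exactly one of the two cross parents and
homozygous in every other parent — are the targets the downstream filter
cascade is meant to recover, because only those segregate 1:1 in the progeny
of the cross (a pseudo-testcross configuration).
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PILEUP_COLUMNS, ReferenceSet

BASES = np.frombuffer(b"ACGT", dtype="S1")
GENOTYPES = ("hom-ref", "het", "hom-alt")

CATEGORIES = (
    "informative-parent-1",
    "informative-parent-2",
    "shared-het",
    "hom-diff",
    "indel",
)

# Sub-stream labels mixed into the seed so each purpose gets an independent,
# reproducible generator.
_STREAM_REFERENCE = 1
_STREAM_VARIANTS = 2
_STREAM_PILEUP = 3


class ConfigurationError(ValueError):
    """A SimConfig violates its invariants."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic cross experiment.

    Defaults mirror a small diploid genome sequenced to moderate depth:
    eight 50 kb scaffolds, a SNP about every 1.4 kb (the genome-wide discovery
    rate of roughly 165,000 candidate sites per 230 Mb), half of the variant
    sites informative for the cross, Poisson mean depth 20 and a 1% per-read
    miscall rate.
    """

    seed: int = 0
    n_scaffolds: int = 8
    scaffold_length: int = 50_000
    snp_density: float = 165_000 / 230e6
    informative_fraction: float = 0.5
    indel_density: float = 1e-4
    repeat_segments: Sequence[tuple[int, int]] = ((200, 2),)
    homopolymer_runs: Sequence[tuple[str, int]] = (("T", 7), ("A", 8))
    mean_depth: float = 20.0
    error_rate: float = 0.01
    parents: Sequence[str] = ("parent1", "parent2", "parent3")

    def validate(self) -> None:
        if self.scaffold_length < 121:
            raise ConfigurationError("scaffold_length must be >= 121 bases")
        if self.n_scaffolds < 1:
            raise ConfigurationError("need at least one scaffold")
        for name, value in [
            ("snp_density", self.snp_density),
            ("informative_fraction", self.informative_fraction),
            ("indel_density", self.indel_density),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        # Zero is allowed here (noise-free truth-recovery runs); the genotype
        # model itself still requires a strictly positive calling error rate.
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must lie in [0, 0.5)")
        if len(self.parents) < 2:
            raise ConfigurationError("need at least two parents (a cross)")
        if len(set(self.parents)) != len(self.parents):
            raise ConfigurationError("parent names must be unique")
        for base, run in self.homopolymer_runs:
            if base not in "ACGT" or run < 6:
                raise ConfigurationError(
                    f"homopolymer runs must be A/C/G/T with length >= 6, got ({base!r}, {run})"
                )
        for length, copies in self.repeat_segments:
            if length < 1 or copies < 2:
                raise ConfigurationError(
                    f"repeat segments need length >= 1 and >= 2 copies, got ({length}, {copies})"
                )

    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]


@dataclasses.dataclass
class TruthRecord:
    """Ground truth for one spiked variant site."""

    scaffold: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype_per_parent: dict[str, str]
    category: str

    def het_parents(self) -> list[str]:
        return [p for p, g in self.genotype_per_parent.items() if g == "het"]


def _rng(cfg: SimConfig, stream: int, label: str = "") -> np.random.Generator:
    """Derive an independent generator for one purpose.

    The stream key mixes the global seed, a purpose constant, and a CRC of the
    label (the parent name for pileup streams), so streams are stable under
    changes elsewhere in the configuration.
    """
    entropy = (int(cfg.seed), stream, zlib.crc32(label.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Reference simulation

def _place_feature(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    scaffold_names: list[str],
    scaffold_length: int,
    feature_length: int,
    max_tries: int = 1000,
) -> tuple[str, int]:
    """Pick a scaffold and 0-based start so the feature overlaps nothing planted."""
    if feature_length > scaffold_length:
        raise ConfigurationError(
            f"feature of length {feature_length} exceeds scaffold length {scaffold_length}"
        )
    for _ in range(max_tries):
        scaffold = scaffold_names[int(rng.integers(len(scaffold_names)))]
        start = int(rng.integers(scaffold_length - feature_length + 1))
        end = start + feature_length
        if all(end <= s or start >= e for s, e in occupied.get(scaffold, [])):
            occupied.setdefault(scaffold, []).append((start, end))
            return scaffold, start
    raise ConfigurationError(
        "could not place all repeat/homopolymer features without overlap; "
        "reduce feature sizes or counts"
    )


def simulate_reference(cfg: SimConfig) -> ReferenceSet:
    """Generate random scaffolds with planted exact repeats and homopolymers.

    Planted intervals (repeat copies and homopolymer runs) are returned as the
    truth repeat annotation on the ReferenceSet, 0-based half-open.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_REFERENCE)
    names = cfg.scaffold_names()

    seqs = {
        name: rng.integers(0, 4, size=cfg.scaffold_length, dtype=np.int8)
        for name in names
    }

    occupied: dict[str, list[tuple[int, int]]] = {}
    annotation: dict[str, list[tuple[int, int]]] = {name: [] for name in names}

    for length, copies in cfg.repeat_segments:
        motif = rng.integers(0, 4, size=length, dtype=np.int8)
        for _ in range(copies):
            scaffold, start = _place_feature(
                rng, occupied, names, cfg.scaffold_length, length
            )
            seqs[scaffold][start : start + length] = motif
            annotation[scaffold].append((start, start + length))

    for base, run in cfg.homopolymer_runs:
        code = "ACGT".index(base)
        scaffold, start = _place_feature(rng, occupied, names, cfg.scaffold_length, run)
        seqs[scaffold][start : start + run] = code
        annotation[scaffold].append((start, start + run))

    sequences = {
        name: BASES[codes].tobytes().decode("ascii") for name, codes in seqs.items()
    }
    return ReferenceSet(
        sequences=sequences,
        repeats={name: sorted(iv) for name, iv in annotation.items()},
    )


# ---------------------------------------------------------------------------
# Variant spiking

def _genotypes_for_category(
    category: str, parents: Sequence[str], rng: np.random.Generator
) -> dict[str, str]:
    genotypes = {p: "hom-ref" for p in parents}
    if category == "informative-parent-1" or category == "informative-parent-2":
        het = parents[0] if category.endswith("1") else parents[1]
        genotypes[het] = "het"
        # Non-het parents may be homozygous for either allele; hom-alt in the
        # other cross parent still yields 1:1 segregation.
        for p in parents:
            if p != het and rng.random() < 0.2:
                genotypes[p] = "hom-alt"
    elif category == "shared-het":
        genotypes[parents[0]] = "het"
        genotypes[parents[1]] = "het"
        if len(parents) > 2 and rng.random() < 0.5:
            genotypes[parents[2]] = "het"
    elif category == "hom-diff":
        genotypes[parents[int(rng.integers(len(parents)))]] = "hom-alt"
    elif category == "indel":
        genotypes[parents[int(rng.integers(len(parents)))]] = "het"
    else:  # pragma: no cover - guarded by CATEGORIES
        raise ValueError(f"unknown category {category!r}")
    return genotypes


def spike_variants(ref: ReferenceSet, cfg: SimConfig) -> list[TruthRecord]:
    """Plant SNP and indel truth records onto the reference.

    SNP counts per scaffold are Poisson with mean ``snp_density * length``;
    a fraction ``informative_fraction`` of SNPs is heterozygous in exactly one
    cross parent (split evenly between parent 1 and parent 2), the remainder
    split evenly between shared-het and hom-diff configurations.  Positions
    are distinct within a scaffold.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_VARIANTS)
    records: list[TruthRecord] = []

    for scaffold, seq in ref.sequences.items():
        length = len(seq)
        n_snps = int(rng.poisson(cfg.snp_density * length))
        n_indels = int(rng.poisson(cfg.indel_density * length))
        total = n_snps + n_indels
        if total == 0:
            continue
        if total > length:
            raise ConfigurationError(
                f"requested {total} variants on a {length}-base scaffold"
            )
        positions = rng.choice(length, size=total, replace=False)

        for i, pos0 in enumerate(positions):
            pos0 = int(pos0)
            ref_allele = seq[pos0]
            is_indel = i >= n_snps
            if is_indel:
                category = "indel"
                alt_allele = "-"
            else:
                u = rng.random()
                if u < cfg.informative_fraction:
                    category = (
                        "informative-parent-1"
                        if rng.random() < 0.5
                        else "informative-parent-2"
                    )
                elif u < cfg.informative_fraction + (1 - cfg.informative_fraction) / 2:
                    category = "shared-het"
                else:
                    category = "hom-diff"
                choices = [b for b in "ACGT" if b != ref_allele]
                alt_allele = choices[int(rng.integers(3))]
            records.append(
                TruthRecord(
                    scaffold=scaffold,
                    position=pos0 + 1,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    genotype_per_parent=_genotypes_for_category(
                        category, cfg.parents, rng
                    ),
                    category=category,
                )
            )

    records.sort(key=lambda r: (r.scaffold, r.position))
    return records


# ---------------------------------------------------------------------------
# Pileup simulation

# Per-read probability of observing the alternate allele for each diploid
# genotype, under a symmetric two-allele miscall model: a hom-ref read shows
# the alternate only through a miscall (rate eps), a het read is a coin flip
# regardless of miscalls, a hom-alt read shows the reference only through a
# miscall.
def _alt_read_probability(genotype: str, error_rate: float) -> float:
    return {"hom-ref": error_rate, "het": 0.5, "hom-alt": 1.0 - error_rate}[genotype]


def simulate_pileup(
    ref: ReferenceSet,
    truth: list[TruthRecord],
    cfg: SimConfig,
    parent: str,
) -> pd.DataFrame:
    """Simulate one parent's per-site allele-count pileup.

    Every position receives Poisson(``mean_depth``) reads; positions with zero
    reads are absent from the output (pileup semantics), so emitted depths
    follow a zero-truncated Poisson.  At SNP truth sites the alternate-read
    count is binomial with the genotype-dependent probability above; at all
    other positions miscalls (rate ``error_rate``) are recorded as
    ``other_count`` since no alternate allele is defined there.  Indel truth
    records contribute ``gap_count`` evidence in carrier parents.
    """
    cfg.validate()
    if parent not in cfg.parents:
        raise ValueError(f"unknown parent {parent!r}; configured: {list(cfg.parents)}")
    rng = _rng(cfg, _STREAM_PILEUP, parent)

    frames = []
    truth_by_scaffold: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        truth_by_scaffold.setdefault(rec.scaffold, []).append(rec)

    for scaffold, seq in ref.sequences.items():
        length = len(seq)
        depth = rng.poisson(cfg.mean_depth, size=length)

        ref_count = depth.copy()
        alt_count = np.zeros(length, dtype=np.int64)
        other_count = rng.binomial(depth, cfg.error_rate)
        gap_count = np.zeros(length, dtype=np.int64)
        alt_base = np.full(length, ".", dtype="U1")

        for rec in truth_by_scaffold.get(scaffold, []):
            i = rec.position - 1
            genotype = rec.genotype_per_parent[parent]
            if rec.category == "indel":
                # Carriers show reads supporting a gap; base counts stay
                # reference-like so the site is indel evidence, not a SNP.
                if genotype != "hom-ref" and depth[i] > 0:
                    gap_count[i] = max(1, int(rng.binomial(depth[i], 0.5)))
                continue
            p_alt = _alt_read_probability(genotype, cfg.error_rate)
            alt_count[i] = rng.binomial(depth[i], p_alt)
            other_count[i] = 0
            alt_base[i] = rec.alt_allele
        ref_count = depth - alt_count - other_count

        keep = depth > 0
        idx = np.flatnonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "pos": idx + 1,
                    "ref_base": np.frombuffer(
                        seq.encode("ascii"), dtype="S1"
                    )[idx].astype("U1"),
                    "depth": depth[idx],
                    "ref_count": ref_count[idx],
                    "alt_base": alt_base[idx],
                    "alt_count": alt_count[idx],
                    "other_count": other_count[idx],
                    "gap_count": gap_count[idx],
                }
            )
        )

    table = pd.concat(frames, ignore_index=True)
    return table[PILEUP_COLUMNS]


# ---------------------------------------------------------------------------
# Truth serialisation

TRUTH_COLUMNS = ["scaffold", "position", "ref_allele", "alt_allele", "genotypes", "category"]


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    """Flatten truth records to a 6-column table (genotypes as p=g;... strings)."""
    rows = [
        {
            "scaffold": r.scaffold,
            "position": r.position,
            "ref_allele": r.ref_allele,
            "alt_allele": r.alt_allele,
            "genotypes": ";".join(f"{p}={g}" for p, g in r.genotype_per_parent.items()),
            "category": r.category,
        }
        for r in truth
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_truth(truth: list[TruthRecord], path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)
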