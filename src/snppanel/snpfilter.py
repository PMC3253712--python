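"""The marker-selection filter cascade.

Raw per-parent genotype calls are merged into cross-level candidate SNPs and
pushed through five stages, each recorded as an audit flag:

1. ``coverage``      — varFilter-style bounds: every parent's depth within
                       [min_depth_varfilter, max_depth] (inclusive).
2. ``spacing``       — no other raw SNP candidate and no gap-evidence site
                       within ``spacing_window`` bases on either side.
3. ``informative``   — exactly one parent heterozygous, every other parent
                       homozygous (either allele), and the heterozygous
                       parent's variant quality strictly above
                       ``min_quality_Q``.  Only such sites segregate 1:1 in
                       the progeny of the cross.
4. ``depth-support`` — minimum per-parent depth at least
                       ``min_reads_supporting`` (the conservative reading of
                       a per-site read-support threshold).
5. ``repeat-mask``   — position outside every annotated repeat interval and
                       outside any homopolymer run of length
                       >= ``homopolymer_min_run`` scanned directly from the
                       reference.

The spacing exclusion set is the *pre-filter* candidate set plus all gap
sites, and removal is symmetric (both neighbours fail): a nearby low-quality
SNP still corrupts an assay probe, whichever of the pair is kept.  Because
spacing is evaluated against that fixed set, stages 2-5 are independent
predicates and commute; the cascade order only determines which failure is
reported first in the audit.

Sites whose parents disagree on the alternate allele are flagged
``triallelic`` and excluded before stage 1 — the two-allele genotype model
does not cover them.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import NO_CALL
from .io import ReferenceSet

VARIANT_GENOTYPES = ("het", "hom-alt")

FILTER_ORDER = ["coverage", "spacing", "informative", "depth-support", "repeat-mask"]

TRIALLELIC = "triallelic"
PASS = "PASS"


class FrameMismatchError(ValueError):
    """Call tables do not share a reference frame."""


@dataclasses.dataclass
class FilterConfig:
    """Thresholds of the cascade.

    Boundary semantics are fixed: depth bounds and the read-support threshold
    are inclusive, the quality threshold is strict (Q = min_quality_Q fails),
    and a neighbour at exactly ``spacing_window`` bases violates spacing.
    """

    min_depth_varfilter: int = 4
    max_depth: int = 100
    spacing_window: int = 60
    min_quality_Q: float = 100.0
    min_reads_supporting: int = 10
    homopolymer_min_run: int = 6

    def validate(self) -> None:
        if not 0 < self.min_depth_varfilter <= self.max_depth:
            raise ValueError("need 0 < min_depth_varfilter <= max_depth")
        if self.spacing_window < 0:
            raise ValueError("spacing_window must be >= 0")
        if self.min_quality_Q < 0 or self.min_reads_supporting < 0:
            raise ValueError("thresholds must be >= 0")
        if self.homopolymer_min_run < 1:
            raise ValueError("homopolymer_min_run must be >= 1")


# ---------------------------------------------------------------------------
# Candidate construction

def gap_sites(calls: Mapping[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    """Positions (1-based) with indel evidence in any parent, per scaffold."""
    sites: dict[str, set[int]] = {}
    for table in calls.values():
        with_gap = table[table["gap_count"] > 0]
        for scaffold, group in with_gap.groupby("scaffold", sort=False):
            sites.setdefault(str(scaffold), set()).update(int(p) for p in group["pos"])
    return {s: np.array(sorted(p), dtype=np.int64) for s, p in sites.items()}


def build_candidates(calls: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-parent call tables into one wide candidate table.

    A raw candidate is any site where at least one parent's MAP genotype is
    het or hom-alt.  The result has one row per candidate with per-parent
    ``genotype:<p>``, ``Q:<p>`` and ``depth:<p>`` columns; a parent with no
    pileup row at the site contributes a no-call with depth 0.
    """
    if not calls:
        raise ValueError("no call tables supplied")
    parents = list(calls)
    scaffold_sets = [s for s in (set(t["scaffold"].unique()) for t in calls.values()) if s]
    if len(scaffold_sets) > 1 and not set.intersection(*scaffold_sets):
        raise FrameMismatchError(
            "call tables share no scaffold names; inputs are on different references"
        )

    indexed = {
        p: t.set_index(["scaffold", "pos"], verify_integrity=True) for p, t in calls.items()
    }
    keys: set[tuple[str, int]] = set()
    for p, t in indexed.items():
        variant = t[t["genotype"].isin(VARIANT_GENOTYPES)]
        keys.update(variant.index)
    index = pd.MultiIndex.from_tuples(
        sorted(keys), names=["scaffold", "pos"]
    ) if keys else pd.MultiIndex.from_arrays([[], []], names=["scaffold", "pos"])

    wide = pd.DataFrame(index=index)
    ref = pd.Series("N", index=index, dtype=object)
    alt = pd.Series(".", index=index, dtype=object)
    triallelic = pd.Series(False, index=index)

    for p in parents:
        sub = indexed[p].reindex(index)
        wide[f"genotype:{p}"] = sub["genotype"].fillna(NO_CALL)
        wide[f"Q:{p}"] = sub["Q"].fillna(0.0)
        wide[f"depth:{p}"] = sub["depth"].fillna(0).astype(np.int64)
        has = sub["ref"].notna()
        ref[has] = sub.loc[has, "ref"]
        p_alt = sub["alt"].fillna(".")
        informative_alt = p_alt != "."
        conflict = informative_alt & (alt != ".") & (alt != p_alt)
        triallelic |= conflict
        alt[informative_alt & ~conflict] = p_alt[informative_alt & ~conflict]

    wide.insert(0, "ref", ref)
    wide.insert(1, "alt", alt)
    wide[TRIALLELIC] = triallelic
    wide.attrs["parents"] = parents
    return wide.reset_index()


def _parents(candidates: pd.DataFrame, parents: Sequence[str] | None) -> list[str]:
    if parents is not None:
        return list(parents)
    found = candidates.attrs.get("parents")
    if found is None:
        found = [c.split(":", 1)[1] for c in candidates.columns if c.startswith("genotype:")]
    return list(found)


# ---------------------------------------------------------------------------
# Stage predicates (each returns a boolean pass mask over the candidate rows)

def coverage_mask(
    candidates: pd.DataFrame, cfg: FilterConfig, parents: Sequence[str] | None = None
) -> pd.Series:
    parents = _parents(candidates, parents)
    ok = pd.Series(True, index=candidates.index)
    for p in parents:
        depth = candidates[f"depth:{p}"]
        ok &= (depth >= cfg.min_depth_varfilter) & (depth <= cfg.max_depth)
    return ok


def spacing_mask(
    candidates: pd.DataFrame,
    gaps: Mapping[str, np.ndarray],
    cfg: FilterConfig,
    exclusion: Mapping[str, np.ndarray] | None = None,
) -> pd.Series:
    """Pass iff no other exclusion-set member lies within the window.

    The exclusion set is the raw (pre-filter) candidate set plus every gap
    site; pass it explicitly via ``exclusion`` when ``candidates`` is already
    a filtered subset, so the screen still sees every raw neighbour.  The
    candidate itself accounts for exactly one member at distance 0.
    """
    if exclusion is None:
        exclusion = {
            str(scaffold): group["pos"].to_numpy(dtype=np.int64)
            for scaffold, group in candidates.groupby("scaffold", sort=False)
        }
    ok = pd.Series(True, index=candidates.index)
    w = cfg.spacing_window
    empty = np.empty(0, dtype=np.int64)
    for scaffold, group in candidates.groupby("scaffold", sort=False):
        scaffold = str(scaffold)
        pos = group["pos"].to_numpy(dtype=np.int64)
        members = np.sort(
            np.concatenate([
                np.asarray(exclusion.get(scaffold, empty), dtype=np.int64),
                np.asarray(gaps.get(scaffold, empty), dtype=np.int64),
            ])
        )
        lo = np.searchsorted(members, pos - w, side="left")
        hi = np.searchsorted(members, pos + w, side="right")
        ok.loc[group.index] = (hi - lo) <= 1
    return ok


def informative_mask(
    candidates: pd.DataFrame, cfg: FilterConfig, parents: Sequence[str] | None = None
) -> pd.Series:
    parents = _parents(candidates, parents)
    genos = np.stack([candidates[f"genotype:{p}"].to_numpy() for p in parents])
    quals = np.stack([candidates[f"Q:{p}"].to_numpy() for p in parents])
    het = genos == "het"
    hom = (genos == "hom-ref") | (genos == "hom-alt")
    one_het = het.sum(axis=0) == 1
    others_hom = (het | hom).all(axis=0)
    het_q = np.where(het, quals, -np.inf).max(axis=0)
    ok = one_het & others_hom & (het_q > cfg.min_quality_Q)
    return pd.Series(ok, index=candidates.index)


def depth_support_mask(
    candidates: pd.DataFrame, cfg: FilterConfig, parents: Sequence[str] | None = None
) -> pd.Series:
    return min_parent_depth(candidates, parents) >= cfg.min_reads_supporting


def min_parent_depth(
    candidates: pd.DataFrame, parents: Sequence[str] | None = None
) -> pd.Series:
    parents = _parents(candidates, parents)
    depths = np.stack([candidates[f"depth:{p}"].to_numpy() for p in parents])
    return pd.Series(depths.min(axis=0), index=candidates.index)


def homopolymer_intervals(seq: str, min_run: int) -> list[tuple[int, int]]:
    """0-based half-open intervals of base runs with length >= min_run."""
    if not seq:
        return []
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.int8)
    boundaries = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(codes)]])
    long_enough = (ends - starts) >= min_run
    return [(int(s), int(e)) for s, e in zip(starts[long_enough], ends[long_enough])]


def _positions_in_intervals(
    pos_1based: np.ndarray, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Membership of 1-based positions in 0-based half-open intervals."""
    if not len(intervals):
        return np.zeros(len(pos_1based), dtype=bool)
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    pos0 = pos_1based - 1
    idx = np.searchsorted(starts, pos0, side="right") - 1
    inside = idx >= 0
    inside[inside] &= pos0[inside] < ends[idx[inside]]
    return inside


def repeat_mask_mask(
    candidates: pd.DataFrame,
    repeats: Mapping[str, Sequence[tuple[int, int]]],
    ref: ReferenceSet,
    cfg: FilterConfig,
) -> pd.Series:
    """Pass iff the position is outside annotated repeats and homopolymers."""
    for scaffold in repeats:
        if scaffold not in ref.sequences:
            warnings.warn(
                f"repeat interval on unknown scaffold {scaffold!r} ignored",
                stacklevel=2,
            )
    ok = pd.Series(True, index=candidates.index)
    for scaffold, group in candidates.groupby("scaffold", sort=False):
        scaffold = str(scaffold)
        if scaffold not in ref.sequences:
            continue
        intervals = list(repeats.get(scaffold, []))
        intervals += homopolymer_intervals(
            ref.sequences[scaffold], cfg.homopolymer_min_run
        )
        pos = group["pos"].to_numpy(dtype=np.int64)
        ok.loc[group.index] = ~_positions_in_intervals(pos, intervals)
    return ok


# ---------------------------------------------------------------------------
# Public stage operations (subset in, subset out)

def prefilter_coverage(candidates: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    return candidates[coverage_mask(candidates, cfg)]


def filter_spacing(
    candidates: pd.DataFrame,
    gaps: Mapping[str, np.ndarray],
    cfg: FilterConfig,
    exclusion: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    return candidates[spacing_mask(candidates, gaps, cfg, exclusion)]


def filter_informative(candidates: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    return candidates[informative_mask(candidates, cfg)]


def filter_depth_support(candidates: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    return candidates[depth_support_mask(candidates, cfg)]


def mask_repeats(
    candidates: pd.DataFrame,
    repeats: Mapping[str, Sequence[tuple[int, int]]],
    ref: ReferenceSet,
    cfg: FilterConfig,
) -> pd.DataFrame:
    return candidates[repeat_mask_mask(candidates, repeats, ref, cfg)]


# ---------------------------------------------------------------------------
# Cascade

def _annotate(candidates: pd.DataFrame, parents: Sequence[str]) -> pd.DataFrame:
    """Add informative_parent, panel Q and min_parent_depth columns.

    The panel quality is the heterozygous parent's variant quality when the
    site has exactly one het parent, otherwise the maximum variant quality
    over parents (the best evidence that the site is variant at all).
    """
    genos = np.stack([candidates[f"genotype:{p}"].to_numpy() for p in parents])
    quals = np.stack([candidates[f"Q:{p}"].to_numpy() for p in parents])
    het = genos == "het"
    one_het = het.sum(axis=0) == 1
    het_idx = np.where(het.any(axis=0), het.argmax(axis=0), -1)
    parent_names = np.array(list(parents) + ["."], dtype=object)
    out = candidates.copy()
    out["informative_parent"] = np.where(one_het, parent_names[het_idx], ".")
    het_q = np.where(het, quals, -np.inf).max(axis=0)
    out["Q"] = np.where(one_het, het_q, quals.max(axis=0))
    out["min_parent_depth"] = min_parent_depth(candidates, parents).to_numpy()
    return out


def run_cascade(
    calls: Mapping[str, pd.DataFrame],
    gaps: Mapping[str, np.ndarray] | None,
    repeats: Mapping[str, Sequence[tuple[int, int]]],
    ref: ReferenceSet,
    cfg: FilterConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all filters; return (retained panel, full audit table).

    The audit table has one row per raw candidate with every stage's
    pass/fail flag and a ``filter`` column holding PASS or the first failing
    stage in cascade order (``triallelic`` pre-empts all stages).  The
    retained panel equals the conjunction of all stage predicates.
    """
    cfg.validate()
    candidates = build_candidates(calls)
    parents = candidates.attrs["parents"]
    if gaps is None:
        gaps = gap_sites(calls)

    flags = pd.DataFrame(index=candidates.index)
    flags["coverage"] = coverage_mask(candidates, cfg, parents)
    flags["spacing"] = spacing_mask(candidates, gaps, cfg)
    flags["informative"] = informative_mask(candidates, cfg, parents)
    flags["depth-support"] = depth_support_mask(candidates, cfg, parents)
    flags["repeat-mask"] = repeat_mask_mask(candidates, repeats, ref, cfg)

    biallelic = ~candidates[TRIALLELIC]
    first_fail = np.full(len(candidates), PASS, dtype=object)
    undecided = biallelic.to_numpy().copy()
    first_fail[~undecided] = TRIALLELIC
    for stage in FILTER_ORDER:
        failing = undecided & ~flags[stage].to_numpy()
        first_fail[failing] = stage
        undecided &= ~failing

    annotated = _annotate(candidates, parents)
    audit = annotated[["scaffold", "pos", "ref", "alt", "Q", "min_parent_depth",
                       "informative_parent"]].copy()
    for stage in FILTER_ORDER:
        audit[stage] = flags[stage]
    audit[TRIALLELIC] = candidates[TRIALLELIC]
    audit["filter"] = first_fail

    retained = annotated[first_fail == PASS].copy()
    retained["filter"] = PASS
    retained.attrs["parents"] = parents
    return retained, audit
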