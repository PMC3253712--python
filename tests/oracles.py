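"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct probability arithmetic,
exhaustive substring scans, per-site predicate loops — and shares no code
with the package's vectorised implementations, so agreement between the two
is evidence, not tautology.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

GENOTYPES = ("hom-ref", "het", "hom-alt")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Genotype model

def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def genotype_likelihoods(ref_count: int, alt_count: int, eps: float) -> list[float]:
    n = ref_count + alt_count
    return [binom_pmf(alt_count, n, p) for p in (eps, 0.5, 1.0 - eps)]


def map_genotype(ref_count: int, alt_count: int, eps: float,
                 prior: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)) -> str:
    """Argmax posterior genotype; first index wins ties (hom-ref < het < hom-alt)."""
    posts = [l * p for l, p in zip(genotype_likelihoods(ref_count, alt_count, eps), prior)]
    return GENOTYPES[max(range(3), key=lambda i: (posts[i], -i))]


def variant_quality(ref_count: int, alt_count: int, eps: float,
                    prior: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)) -> float:
    """-10 log10 posterior(hom-ref), in log space to survive extreme counts."""
    n = ref_count + alt_count
    k = alt_count
    logs = []
    for p, pr in zip((eps, 0.5, 1.0 - eps), prior):
        logs.append(
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * math.log(p) + (n - k) * math.log(1.0 - p) + math.log(pr)
        )
    m = max(logs)
    log_post_homref = logs[0] - (m + math.log(sum(math.exp(x - m) for x in logs)))
    return max(0.0, -10.0 * log_post_homref / math.log(10.0))


def bayes_accuracy(mean_depth: float, eps: float, max_depth: int = 120) -> float:
    """Expected MAP accuracy for genotypes drawn uniformly, depth ~ Poisson>=1.

    Direct summation: for each depth, each alternate-read count, credit the
    true genotype's probability of producing a count the MAP rule maps back
    to it.  Depths above ``max_depth`` carry negligible Poisson mass.
    """
    # zero-truncated Poisson weights
    weights = {}
    log_norm = math.log1p(-math.exp(-mean_depth))
    for n in range(1, max_depth + 1):
        weights[n] = math.exp(
            -mean_depth + n * math.log(mean_depth) - math.lgamma(n + 1) - log_norm
        )
    acc = 0.0
    for g_idx, p_alt in enumerate((eps, 0.5, 1.0 - eps)):
        for n, w in weights.items():
            correct = 0.0
            for k in range(n + 1):
                if map_genotype(n - k, k, eps) == GENOTYPES[g_idx]:
                    correct += binom_pmf(k, n, p_alt)
            acc += w * correct / 3.0
    return acc


# ---------------------------------------------------------------------------
# Filter cascade as a conjunction of per-site predicates

def conjunction_retained(
    calls: Mapping[str, "pd.DataFrame"],  # noqa: F821 - typing only
    gaps: Mapping[str, Sequence[int]],
    repeats: Mapping[str, Sequence[tuple[int, int]]],
    sequences: Mapping[str, str],
    *,
    min_depth: int = 4,
    max_depth: int = 100,
    window: int = 60,
    min_q: float = 100.0,
    min_support: int = 10,
    homopolymer_min_run: int = 6,
) -> set[tuple[str, int]]:
    """Retained (scaffold, pos) set by evaluating every predicate per site."""
    parents = list(calls)
    by_parent = {
        p: {(row.scaffold, row.pos): row for row in table.itertuples(index=False)}
        for p, table in calls.items()
    }
    candidate_keys = sorted(
        {
            key
            for p in parents
            for key, row in by_parent[p].items()
            if row.genotype in ("het", "hom-alt")
        }
    )
    candidate_pos: dict[str, list[int]] = {}
    for scaffold, pos in candidate_keys:
        candidate_pos.setdefault(scaffold, []).append(pos)

    homopolymer_pos: dict[str, set[int]] = {}
    for scaffold, seq in sequences.items():
        inside: set[int] = set()
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= homopolymer_min_run:
                inside.update(range(i, j))
            i = j
        homopolymer_pos[scaffold] = inside

    retained: set[tuple[str, int]] = set()
    for scaffold, pos in candidate_keys:
        rows = {p: by_parent[p].get((scaffold, pos)) for p in parents}

        alts = {r.alt for r in rows.values() if r is not None and r.alt != "."}
        if len(alts) > 1:
            continue  # triallelic

        depths = {p: (0 if r is None else r.depth) for p, r in rows.items()}
        if not all(min_depth <= d <= max_depth for d in depths.values()):
            continue

        near = any(
            q != pos and abs(q - pos) <= window for q in candidate_pos.get(scaffold, [])
        ) or any(abs(g - pos) <= window for g in gaps.get(scaffold, []))
        if near:
            continue

        genos = {p: ("no-call" if r is None else r.genotype) for p, r in rows.items()}
        hets = [p for p, g in genos.items() if g == "het"]
        homs = [p for p, g in genos.items() if g in ("hom-ref", "hom-alt")]
        if not (len(hets) == 1 and len(homs) == len(parents) - 1):
            continue
        if not rows[hets[0]].Q > min_q:
            continue

        if min(depths.values()) < min_support:
            continue

        pos0 = pos - 1
        if any(s <= pos0 < e for s, e in repeats.get(scaffold, [])):
            continue
        if pos0 in homopolymer_pos.get(scaffold, set()):
            continue

        retained.add((scaffold, pos))
    return retained


# ---------------------------------------------------------------------------
# Substring uniqueness

def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        hit = haystack.find(needle, start)
        if hit < 0:
            return count
        count += 1
        start = hit + 1


def exhaustive_unique(context: str, sequences: Mapping[str, str], k: int) -> bool:
    """True iff every k-window of context occurs exactly once over both strands."""
    if "N" in context:
        return False
    for i in range(len(context) - k + 1):
        window = context[i : i + k]
        rc = reverse_complement(window)
        total = sum(count_overlapping(seq, window) for seq in sequences.values())
        if rc != window:
            total += sum(count_overlapping(seq, rc) for seq in sequences.values())
        if total != 1:
            return False
    return True
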