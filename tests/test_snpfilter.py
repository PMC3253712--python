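"""Filter cascade: documented boundary behaviour, audit bookkeeping, stage
commutation, and site-for-site agreement with the brute-force conjunction
oracle on synthetic data."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from snppanel import FilterConfig
from snppanel.io import ReferenceSet
from snppanel.snpfilter import (
    FrameMismatchError,
    build_candidates,
    coverage_mask,
    depth_support_mask,
    filter_spacing,
    gap_sites,
    homopolymer_intervals,
    informative_mask,
    mask_repeats,
    prefilter_coverage,
    repeat_mask_mask,
    run_cascade,
    spacing_mask,
)

# a 1 kb scaffold with no homopolymer runs at all
REF = ReferenceSet(sequences={"s1": "ACGT" * 250})

CFG = FilterConfig()


def call_frame(rows) -> pd.DataFrame:
    """rows: (pos, genotype, Q, depth[, gap_count, alt, scaffold])"""
    records = []
    for row in rows:
        pos, genotype, q, depth = row[:4]
        gap = row[4] if len(row) > 4 else 0
        alt = row[5] if len(row) > 5 else ("G" if genotype != "hom-ref" else ".")
        scaffold = row[6] if len(row) > 6 else "s1"
        records.append(
            {
                "scaffold": scaffold, "pos": pos,
                "ref": REF.sequences["s1"][(pos - 1) % 1000], "alt": alt,
                "genotype": genotype, "Q": float(q), "depth": depth, "gap_count": gap,
            }
        )
    return pd.DataFrame(
        records,
        columns=["scaffold", "pos", "ref", "alt", "genotype", "Q", "depth", "gap_count"],
    )


def two_parent_candidates(p1_rows, p2_rows):
    calls = {"p1": call_frame(p1_rows), "p2": call_frame(p2_rows)}
    return build_candidates(calls), calls


class TestCoverage:
    @pytest.mark.parametrize(
        "d1,d2,kept",
        [
            (3, 50, False),   # below the minimum in one parent
            (4, 100, True),   # both bounds inclusive
            (101, 50, False), # above the maximum
            (0, 50, False),   # degenerate
        ],
    )
    def test_depth_bounds(self, d1, d2, kept):
        cands, _ = two_parent_candidates(
            [(101, "het", 150, d1)], [(101, "hom-ref", 0, d2)]
        )
        assert coverage_mask(cands, CFG).tolist() == [kept]
        assert len(prefilter_coverage(cands, CFG)) == int(kept)

    def test_disjoint_scaffolds_raise_frame_mismatch(self):
        calls = {
            "p1": call_frame([(101, "het", 150, 20)]),
            "p2": call_frame([(101, "het", 150, 20, 0, "G", "other")]),
        }
        with pytest.raises(FrameMismatchError):
            build_candidates(calls)


class TestSpacing:
    def make(self, positions, gaps=()):
        p1 = [(pos, "het", 150, 20) for pos in positions]
        p1 += [(pos, "hom-ref", 0, 20, 3) for pos in gaps]
        cands, calls = two_parent_candidates(
            p1, [(pos, "hom-ref", 0, 20) for pos in positions]
        )
        return cands, gap_sites(calls)

    def test_pair_just_outside_window_both_kept(self):
        cands, gaps = self.make([100, 161])
        assert spacing_mask(cands, gaps, CFG).tolist() == [True, True]

    def test_pair_at_window_boundary_both_dropped(self):
        cands, gaps = self.make([100, 160])
        assert spacing_mask(cands, gaps, CFG).tolist() == [False, False]

    def test_single_candidate_kept(self):
        cands, gaps = self.make([500])
        assert spacing_mask(cands, gaps, CFG).tolist() == [True]

    def test_gap_site_within_window_drops_candidate(self):
        cands, gaps = self.make([300], gaps=[340])
        assert spacing_mask(cands, gaps, CFG).tolist() == [False]

    def test_gap_just_outside_window_is_harmless(self):
        cands, gaps = self.make([300], gaps=[361])
        assert spacing_mask(cands, gaps, CFG).tolist() == [True]

    def test_subset_still_sees_raw_neighbours_via_exclusion(self):
        cands, gaps = self.make([100, 140])
        exclusion = {"s1": cands["pos"].to_numpy()}
        subset = cands.iloc[[0]]
        kept = filter_spacing(subset, gaps, CFG, exclusion=exclusion)
        assert len(kept) == 0


class TestInformative:
    @pytest.mark.parametrize(
        "g1,g2,q,kept",
        [
            ("het", "hom-ref", 150, True),
            ("het", "hom-alt", 150, True),   # still 1:1 in the progeny
            ("het", "het", 150, False),      # both parents polymorphic
            ("hom-alt", "hom-ref", 150, False),  # no het parent at all
            ("het", "hom-ref", 100, False),  # strict inequality at Q = 100
            ("het", "hom-ref", 100.01, True),
            ("het", "no-call", 150, False),  # missing genotype drops the site
        ],
    )
    def test_exactly_one_het_parent_above_q(self, g1, g2, q, kept):
        cands, _ = two_parent_candidates(
            [(101, g1, q if g1 == "het" else 0, 20)],
            [(101, g2, q if g2 == "het" else 0, 20)],
        )
        if len(cands) == 0:  # neither parent variant -> not even a candidate
            assert not kept
            return
        assert informative_mask(cands, CFG).tolist() == [kept]

    def test_informative_parent_identity_recorded(self):
        cands, calls = two_parent_candidates(
            [(101, "hom-ref", 0, 20)], [(101, "het", 150, 20)]
        )
        panel, audit = run_cascade(calls, None, {}, REF, CFG)
        assert audit["informative_parent"].tolist() == ["p2"]


class TestDepthSupport:
    @pytest.mark.parametrize("d,kept", [(9, False), (10, True), (0, False)])
    def test_min_parent_depth_threshold(self, d, kept):
        cands, _ = two_parent_candidates(
            [(101, "het", 150, d)], [(101, "hom-ref", 0, 50)]
        )
        assert depth_support_mask(cands, CFG).tolist() == [kept]


class TestRepeatMask:
    def test_bed_half_open_containment(self):
        repeats = {"s1": [(100, 200)]}
        # 1-based 150 lies inside [100, 200); 1-based 200 is 0-based 199 -> inside;
        # 1-based 201 is 0-based 200 -> just outside the half-open end
        cands, _ = two_parent_candidates(
            [(150, "het", 150, 20), (201, "het", 150, 20)],
            [(150, "hom-ref", 0, 20), (201, "hom-ref", 0, 20)],
        )
        mask = repeat_mask_mask(cands, repeats, REF, CFG)
        assert mask.tolist() == [False, True]
        assert mask_repeats(cands, repeats, REF, CFG)["pos"].tolist() == [201]

    def test_snp_inside_homopolymer_run_dropped(self):
        seq = "ACGT" * 100 + "TTTTTTT" + "ACGT" * 100
        ref = ReferenceSet(sequences={"s1": seq})
        pos_in_run = 404  # 1-based, inside the planted TTTTTTT
        cands, _ = two_parent_candidates(
            [(pos_in_run, "het", 150, 20)], [(pos_in_run, "hom-ref", 0, 20)]
        )
        assert repeat_mask_mask(cands, {}, ref, CFG).tolist() == [False]

    def test_unknown_scaffold_interval_warns_and_is_ignored(self):
        cands, _ = two_parent_candidates(
            [(500, "het", 150, 20)], [(500, "hom-ref", 0, 20)]
        )
        with pytest.warns(UserWarning, match="unknown scaffold"):
            mask = repeat_mask_mask(cands, {"sX": [(0, 1000)]}, REF, CFG)
        assert mask.tolist() == [True]

    def test_homopolymer_interval_scanner(self):
        assert homopolymer_intervals("AAAAAACGT", 6) == [(0, 6)]
        assert homopolymer_intervals("ACGTACGT", 6) == []
        assert homopolymer_intervals("ACGGGGGGGT", 6) == [(2, 9)]


class TestCascade:
    def test_empty_input_empty_outputs(self):
        calls = {"p1": call_frame([]), "p2": call_frame([])}
        panel, audit = run_cascade(calls, None, {}, REF, CFG)
        assert len(panel) == 0 and len(audit) == 0

    def test_triallelic_site_excluded_before_stages(self):
        calls = {
            "p1": call_frame([(101, "het", 150, 20, 0, "G")]),
            "p2": call_frame([(101, "het", 150, 20, 0, "C")]),
        }
        panel, audit = run_cascade(calls, None, {}, REF, CFG)
        assert audit["filter"].tolist() == ["triallelic"]
        assert len(panel) == 0

    def test_audit_partitions_candidates_and_orders_failures(self, small_result):
        audit = small_result.audit
        assert len(audit) >= 10
        # every candidate appears once, labelled PASS or a stage name
        assert audit.duplicated(["scaffold", "pos"]).sum() == 0
        stage_cols = ["coverage", "spacing", "informative", "depth-support", "repeat-mask"]
        passing = audit[audit["filter"] == "PASS"]
        assert passing[stage_cols].all(axis=None)
        # a reported first failure really is a failure, and earlier stages passed
        order = dict(zip(stage_cols, range(len(stage_cols))))
        failed = audit[audit["filter"].isin(stage_cols)]
        for _, row in failed.iterrows():
            assert not row[row["filter"]]
            for earlier in stage_cols[: order[row["filter"]]]:
                assert row[earlier]

    def test_retained_equals_conjunction_of_flags(self, small_result):
        audit = small_result.audit
        stage_flags = audit[["coverage", "spacing", "informative",
                             "depth-support", "repeat-mask"]]
        conj = stage_flags.all(axis=1) & ~audit["triallelic"]
        assert (conj == (audit["filter"] == "PASS")).all()
        assert len(small_result.panel) == int(conj.sum())

    def test_cascade_agrees_with_brute_force_oracle(self, small_result, small_cfg):
        ref = small_result.reference
        calls = small_result.calls
        gaps = {s: list(p) for s, p in gap_sites(calls).items()}
        expected = oracles.conjunction_retained(
            calls, gaps, ref.repeats, ref.sequences
        )
        got = {
            (row.scaffold, row.pos)
            for row in small_result.panel.itertuples(index=False)
        }
        assert got == expected

    def test_post_coverage_stages_commute(self, small_result):
        """With spacing anchored to the raw candidate set, the last four
        stages are order-independent."""
        cands = build_candidates(small_result.calls)
        gaps = gap_sites(small_result.calls)
        exclusion = {
            str(s): g["pos"].to_numpy() for s, g in cands.groupby("scaffold")
        }
        cfg = CFG
        ref = small_result.reference

        def stage(name, frame):
            if name == "spacing":
                return frame[spacing_mask(frame, gaps, cfg, exclusion=exclusion)]
            if name == "informative":
                return frame[informative_mask(frame, cfg)]
            if name == "depth":
                return frame[depth_support_mask(frame, cfg)]
            return frame[repeat_mask_mask(frame, {}, ref, cfg)]

        start = prefilter_coverage(cands[~cands["triallelic"]], cfg)
        results = []
        for order in itertools.permutations(["spacing", "informative", "depth", "mask"]):
            frame = start
            for name in order:
                frame = stage(name, frame)
            results.append(set(zip(frame["scaffold"], frame["pos"])))
        assert all(r == results[0] for r in results[1:])

    def test_subset_chain(self, small_result):
        cands = build_candidates(small_result.calls)
        kept = prefilter_coverage(cands, CFG)
        assert len(kept) <= len(cands)
        deeper = kept[depth_support_mask(kept, CFG)]
        assert set(zip(deeper["scaffold"], deeper["pos"])) <= set(
            zip(kept["scaffold"], kept["pos"])
        )


class TestTruthRecovery:
    def test_noise_free_panel_recovers_informative_truth(self):
        """At eps = 0 and deep coverage the retained panel equals exactly the
        truth sites that are informative, well spaced, outside repeats and
        depth-qualified (quality evaluated on the realised read counts)."""
        from snppanel import SimConfig, run_pipeline

        cfg = SimConfig(seed=77, n_scaffolds=2, scaffold_length=20_000,
                        snp_density=2e-3, indel_density=2e-4, error_rate=0.0,
                        mean_depth=40.0)
        result = run_pipeline(cfg)

        ref = result.reference
        gaps = {s: list(p) for s, p in gap_sites(result.calls).items()}
        expected = oracles.conjunction_retained(
            result.calls, gaps, ref.repeats, ref.sequences
        )
        got = {(r.scaffold, r.pos) for r in result.panel.itertuples(index=False)}
        assert got == expected

        truth_by_key = {(t.scaffold, t.position): t for t in result.truth}
        # precision 1 against the truth: every retained site is a true
        # informative SNP with the right informative parent
        for row in result.panel.itertuples(index=False):
            truth = truth_by_key[(row.scaffold, row.pos)]
            assert truth.category.startswith("informative")
            assert truth.het_parents() == [row.informative_parent]
            assert truth.alt_allele == row.alt
        # and the panel is non-trivial at this density
        assert len(result.panel) >= 10
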