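"""Region scanners, coordinate mapping and selective-class profiling."""

import re

import numpy as np
import pytest

from protsel import domains
from protsel.seqio import CodonAlignment
from protsel.selection_tests import SitePosterior


def brute_force_phospho(seq, kinase):
    """Independent oracle: position-by-position membership checks."""
    seq = seq.upper()
    hits = []
    S, RK, DE = set("ST"), set("RK"), set("DE")
    for i in range(len(seq)):
        if kinase == "PKC" and i + 3 <= len(seq):
            if seq[i] in S and seq[i + 2] in RK:
                hits.append((i, i + 3))
        if kinase == "PKA" and i + 4 <= len(seq):
            if seq[i] in RK and seq[i + 1] in RK and seq[i + 3] in S:
                hits.append((i, i + 4))
        if kinase == "CK2" and i + 4 <= len(seq):
            if seq[i] in S and seq[i + 3] in DE:
                hits.append((i, i + 4))
    return hits


def brute_force_anchoring_runs(seq):
    """All maximal R/K runs of length >= 3 (run detection oracle)."""
    runs, start = [], None
    for i, ch in enumerate(seq + "$"):
        if ch in "RK":
            if start is None:
                start = i
        else:
            if start is not None and i - start >= 3:
                runs.append((start, i))
            start = None
    return runs


class TestAnchoring:
    def test_flanked_run_reported(self):
        regions = domains.scan_anchoring("CYRRRRSC", flank_window=3)
        assert len(regions) == 1
        r = regions[0]
        assert r.start <= 2 and r.end >= 6  # covers the RRRR run

    def test_no_cysteine_no_region(self):
        assert domains.scan_anchoring("ARRRA") == []

    def test_short_run_ignored(self):
        assert domains.scan_anchoring("CRKC") == []

    def test_both_mode_stricter(self):
        seq = "CARRRKAAAA"  # Cys on the left only
        assert len(domains.scan_anchoring(seq, flank_mode="any")) == 1
        assert domains.scan_anchoring(seq, flank_mode="both") == []

    def test_idempotent(self):
        seq = "CRRRRCAKKKC"
        assert domains.scan_anchoring(seq) == domains.scan_anchoring(seq)

    def test_runs_match_oracle_on_random_peptides(self):
        rng = np.random.default_rng(7)
        aa = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(300):
            seq = "".join(rng.choice(list(aa), size=rng.integers(5, 120)))
            got = [
                (m.start(), m.end()) for m in re.finditer(r"[RK]{3,}", seq)
            ]
            assert got == brute_force_anchoring_runs(seq)


class TestPhospho:
    @pytest.mark.parametrize(
        "seq,kinase,expected",
        [
            ("ASRK", "PKC", [(1, 4)]),
            ("RRAS", "PKA", [(0, 4)]),
            ("SAAD", "CK2", [(0, 4)]),
            ("AAAA", "PKC", []),
        ],
    )
    def test_examples(self, seq, kinase, expected):
        got = [
            (r.start, r.end) for r in domains.scan_phospho(seq, {kinase})
        ]
        assert got == expected

    def test_unknown_kinase_rejected(self):
        with pytest.raises(ValueError):
            domains.scan_phospho("ASRK", {"PKZ"})

    def test_scanners_match_brute_force_oracle(self):
        """1000 random peptides, all three kinases, vs the independent
        position-by-position oracle."""
        rng = np.random.default_rng(99)
        aa = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(1000):
            seq = "".join(rng.choice(list(aa), size=rng.integers(1, 200)))
            for kin in ("PKC", "PKA", "CK2"):
                got = sorted(
                    (r.start, r.end)
                    for r in domains.scan_phospho(seq, {kin})
                )
                assert got == sorted(brute_force_phospho(seq, kin))

    def test_overlapping_matches_all_reported(self):
        # SSRK: S at 0 matches S-S-R, S at 1 matches S-R-K
        got = [(r.start, r.end) for r in domains.scan_phospho("SSRK", {"PKC"})]
        assert got == [(0, 3), (1, 4)]


class TestMapConfiguredSites:
    def test_ungapped_identity_mapping(self):
        aln = CodonAlignment(["ref", "x"], ["ATGAAACGT", "ATGAAACGG"])
        regions = domains.map_configured_sites(aln, [0, 2], "cleavage", "ref")
        assert [(r.start, r.end) for r in regions] == [(0, 1), (2, 3)]

    def test_gap_shifts_mapping(self):
        # reference has a 2-codon gap before ungapped position 5
        ref = "ATG" * 5 + "---" * 2 + "ATG" * 2
        other = "ATG" * 9
        aln = CodonAlignment(["ref", "x"], [ref, other])
        regions = domains.map_configured_sites(aln, [5], "cleavage", "ref")
        assert regions[0].interval == (7, 8)

    def test_fourteen_sites_give_fourteen_regions(self):
        aln = CodonAlignment(["ref"], ["ATG" * 40])
        regions = domains.map_configured_sites(
            aln, list(range(14)), "cleavage", "ref"
        )
        assert len(regions) == 14

    def test_position_beyond_reference_rejected(self):
        aln = CodonAlignment(["ref"], ["ATGATG"])
        with pytest.raises(IndexError):
            domains.map_configured_sites(aln, [5], "cleavage", "ref")

    def test_missing_reference_rejected(self):
        aln = CodonAlignment(["x"], ["ATG"])
        with pytest.raises(KeyError):
            domains.map_configured_sites(aln, [0], "cleavage", "ref")


def _posterior_from_classes(classes):
    classes = np.asarray(classes)
    return SitePosterior(
        model_id="M2a",
        class_probs=np.eye(3)[classes - 1],
        mean_omega=np.zeros(len(classes)),
        se_omega=np.zeros(len(classes)),
        assigned_class=classes,
        ps_allowed=True,
    )


class TestProfileRegions:
    def test_hand_counted_percentages(self):
        post = _posterior_from_classes([1, 1, 2, 3, 2, 2, 1, 3, 2, 1])
        annot = domains.DomainAnnotation(
            [("anchoring", (2, 6), "scanned")]
        )
        prof = domains.profile_regions(post, annot)
        assert prof["anchoring"]["percent"] == {1: 0.0, 2: 75.0, 3: 25.0}
        assert prof["anchoring"]["n_sites"] == 4

    def test_all_class2_reports_0_100_0(self):
        post = _posterior_from_classes([2] * 12)
        annot = domains.DomainAnnotation([
            ("anchoring", (0, 4), "scanned"),
            ("phospho_PKC", (5, 9), "scanned"),
        ])
        prof = domains.profile_regions(post, annot)
        for rtype in ("anchoring", "phospho_PKC"):
            assert prof[rtype]["percent"] == {1: 0.0, 2: 100.0, 3: 0.0}

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        post = _posterior_from_classes(rng.integers(1, 4, size=60))
        annot = domains.DomainAnnotation([
            ("anchoring", (0, 20), "scanned"),
            ("cleavage", (30, 45), "configured"),
        ])
        prof = domains.profile_regions(post, annot)
        for rec in prof.values():
            assert sum(rec["percent"].values()) == pytest.approx(100.0, abs=0.05)

    def test_ps_sites_intersected(self):
        post = _posterior_from_classes([1, 3, 1, 1, 3, 1])
        post.pp95 = [1, 4]
        annot = domains.DomainAnnotation([("anchoring", (0, 3), "scanned")])
        prof = domains.profile_regions(post, annot)
        assert prof["anchoring"]["positively_selected"] == [1]
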