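"""LRTs, the clade decision rule, site suites and BEB classification."""

import itertools

import numpy as np
import pytest

from protsel import codon_model as cm
from protsel import selection_tests as st
from protsel import synthetic_data as sd
from protsel.synthetic_data import _f3x4_freqs
from protsel.trees import Phylogeny


def _fake_fit(model_id, lnl, n_params):
    """Minimal FitResult stand-in for pure-logic LRT tests."""
    spec = cm.CodonModelSpec(2.0, np.full(61, 1 / 61), 0.5)
    return cm.FitResult(
        model_id=model_id, lnL=lnl, spec=spec, params={},
        branch_lengths=np.zeros(1), branch_table=None, n_params=n_params,
        converged=True, tree=None,
    )


class TestLRT:
    def test_identical_fits_ns(self):
        r = st.lrt(_fake_fit("M1a", -100.0, 3), _fake_fit("M2a", -100.0, 5))
        assert r.two_delta_l == 0.0 and r.verdict == "ns"

    def test_printed_value_9_71_is_double_starred(self):
        """2*dl = 9.71 on 2 df exceeds the 0.01 critical value (9.21)."""
        r = st.lrt(
            _fake_fit("M1a", -100.0, 3), _fake_fit("M2a", -100.0 + 9.71 / 2, 5)
        )
        assert r.df == 2 and r.p_value < 0.01 and r.verdict == "**"

    def test_printed_value_7_34_is_single_starred(self):
        """2*dl = 7.34 on 2 df is between the 0.05 (5.99) and 0.01 cutoffs."""
        r = st.lrt(
            _fake_fit("M7", -100.0, 2), _fake_fit("M8", -100.0 + 7.34 / 2, 4)
        )
        assert r.df == 2 and 0.01 < r.p_value < 0.05 and r.verdict == "*"

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError):
            st.lrt(_fake_fit("M2a", -100.0, 5), _fake_fit("M7", -99.0, 2))

    def test_small_negative_clamped(self):
        r = st.lrt(_fake_fit("M1a", -100.0, 3), _fake_fit("M2a", -100.01, 5))
        assert r.two_delta_l == 0.0


class TestCladeDecisionRule:
    @pytest.mark.parametrize(
        "omega,sig1,sig2,expected",
        [
            (2.44, True, True, "Positive"),     # printed protamine-1 pattern
            (2.75, True, False, "Relaxation"),  # printed cleaved-Prm2 pattern
            (1.66, True, False, "Relaxation"),  # printed mature-Prm2 pattern
            (0.4, False, False, "None"),
            (0.4, False, True, "None"),
            (0.8, True, True, "None"),   # both significant but omega < 1
            (3.0, False, True, "None"),
        ],
    )
    def test_rule_table(self, omega, sig1, sig2, expected):
        assert st.decide_clade_label(omega, sig1, sig2) == expected

    def test_rule_is_exhaustive_and_exclusive(self):
        for sig1, sig2, above in itertools.product([False, True], repeat=3):
            label = st.decide_clade_label(2.0 if above else 0.5, sig1, sig2)
            assert label in ("Positive", "Relaxation", "None")


@pytest.fixture(scope="module")
def clade_world():
    """Positive-selection world on the 16-taxon clade tree, small Lc."""
    tree = sd.clade_tree()
    fg = tree.clade_branches(sd.CRICETIDAE_TAXA, include_stem=True)
    struct = {b: (3.0 if b in fg else 0.3) for b in tree.branch_ids()}
    spec = cm.CodonModelSpec(2.0, _f3x4_freqs(), struct, "F3X4")
    aln, _ = sd.simulate_codon_alignment(tree, spec, 400, seed=77)
    return tree, fg, aln


@pytest.fixture(scope="module")
def clade_fits(clade_world):
    tree, fg, aln = clade_world
    return st.fit_clade_suite(
        aln, tree, sd.CRICETIDAE_TAXA, include_stem=True,
        optimize_branch_lengths=False, n_starts=1, seed=0,
    )


class TestCladeSuite:
    def test_nesting_holds(self, clade_fits):
        m1, m2, m3 = clade_fits
        assert m2.lnL <= m3.lnL + 1e-6
        assert m1.lnL <= m3.lnL + 1e-6
        assert m3.n_params == m1.n_params + 1 == m2.n_params + 1

    def test_positive_world_classified_positive(self, clade_fits):
        decision = st.classify_clade(*clade_fits)
        assert decision.label == "Positive"
        assert decision.foreground_omega > 1

    def test_null_world_omegas_agree(self):
        """Single-omega simulation: the two-ratio estimates coincide."""
        tree = sd.clade_tree()
        spec = cm.CodonModelSpec(2.0, _f3x4_freqs(), 0.5, "F3X4")
        aln, _ = sd.simulate_codon_alignment(tree, spec, 600, seed=13)
        fg = tree.clade_branches(sd.CRICETIDAE_TAXA, include_stem=True)
        m3 = cm.fit(aln, tree, "two-ratio", foreground=fg,
                    optimize_branch_lengths=False, n_starts=1)
        assert abs(m3.params["omega_fg"] - m3.params["omega_bg"]) < 0.2

    def test_non_clade_foreground_rejected(self, clade_world):
        tree, _, aln = clade_world
        with pytest.raises(ValueError):
            st.fit_clade_suite(
                aln, tree, ["Microtus_arvalis", "Mus_musculus"],
                optimize_branch_lengths=False, n_starts=1,
            )


class TestSiteSuite:
    def test_m8_world_designations(self):
        """Strong-selection M8 world: the suite runs end to end and the
        selection models win the LRTs."""
        tree = sd.site_tree()
        mix = cm.SiteMixtureSpec(
            "M8", classes=[(0.3, 3.5)], beta=(0.3, 1.0), beta_weight=0.7,
            ncat=10,
        )
        spec = cm.CodonModelSpec(2.0, _f3x4_freqs(), mix, "F3X4")
        aln, _ = sd.simulate_codon_alignment(tree, spec, 200, seed=5)
        suite = st.fit_site_suite(
            aln, tree, optimize_branch_lengths=False, n_starts=1, seed=0,
            fixed={"kappa": 2.0},
        )
        assert suite.lrt_m1a_m2a.two_delta_l >= 0
        assert suite.designation_m7_m8 == "M8 (beta and omega)"
        assert suite.fits["M8"].params["omega_s"] > 1.5

    def test_neutral_designation_when_ns(self):
        r_null = _fake_fit("M1a", -500.0, 3)
        r_alt = _fake_fit("M2a", -499.5, 5)
        t = st.lrt(r_null, r_alt)
        assert t.verdict == "ns"
        assert ("M2a (selection)" if t.significant else "M1a (neutral)") == \
            "M1a (neutral)"


class TestBEB:
    def test_posteriors_sum_to_one(self, m2a_fit):
        tree, aln, truth, r = m2a_fit
        post = st.beb_classify(aln, tree, r)
        assert np.abs(post.class_probs.sum(axis=1) - 1).max() < 1e-10

    def test_one_point_grid_equals_neb(self, m2a_fit):
        tree, aln, truth, r = m2a_fit
        neb = st.beb_classify(aln, tree, r, neb=True)
        one = st.beb_classify(aln, tree, r, grid_size=1)
        assert np.allclose(neb.class_probs, one.class_probs)
        assert neb.method == "NEB"

    def test_m1a_cannot_flag(self, m2a_sim):
        tree, aln, truth, _spec = m2a_sim
        r1 = cm.fit(aln, tree, "M1a", optimize_branch_lengths=False,
                    n_starts=1)
        post = st.beb_classify(aln, tree, r1)
        assert not post.ps_allowed and post.pp95 == []
        summary = st.summarize_site_classes(post)
        assert summary.positively_selected == ["not allowed"]

    def test_true_selected_sites_enriched(self, m2a_fit):
        """Posterior class-3 mass concentrates on truly selected sites."""
        tree, aln, truth, r = m2a_fit
        post = st.beb_classify(aln, tree, r)
        tc = np.array(truth.site_classes)
        pp3 = post.class_probs[:, 2]
        assert pp3[tc == 2].mean() > pp3[tc != 2].mean()

    def test_m1a_class2_site_assignment(self, m2a_sim):
        tree, aln, truth, _spec = m2a_sim
        r1 = cm.fit(aln, tree, "M1a", optimize_branch_lengths=False,
                    n_starts=1)
        post = st.beb_classify(aln, tree, r1)
        # classes can only be 1 or 2 under M1a
        assert set(np.unique(post.assigned_class)) <= {1, 2}


class TestSummaries:
    def test_all_class1(self):
        s = st.summary_from_assignments(np.ones(50, dtype=int))
        assert s.overall == {1: 100.0, 2: 0.0, 3: 0.0}

    def test_printed_41_51_8_split(self):
        """A 153-site assignment vector with the printed composition."""
        n = 153
        n1 = round(0.41 * n)
        n3 = round(0.08 * n)
        vec = np.array([1] * n1 + [2] * (n - n1 - n3) + [3] * n3)
        s = st.summary_from_assignments(vec)
        assert abs(s.overall[1] - 41) < 1.0
        assert abs(s.overall[2] - 51) < 1.0
        assert abs(s.overall[3] - 8) < 1.0

    def test_region_counts_match_hand_count(self):
        from protsel.domains import DomainAnnotation

        vec = np.array([1, 1, 2, 3, 2, 2, 1, 3, 2, 1])
        annot = DomainAnnotation([("anchoring", (2, 6), "configured")])
        s = st.summary_from_assignments(vec, annot)
        # region covers sites 2..5: classes 2,3,2,2 -> 0/75/25
        assert s.per_region["anchoring"] == {1: 0.0, 2: 75.0, 3: 25.0}

    def test_region_outside_alignment_rejected(self):
        from protsel.domains import DomainAnnotation

        vec = np.ones(5, dtype=int)
        annot = DomainAnnotation([("anchoring", (3, 9), "configured")])
        with pytest.raises(IndexError):
            st.summary_from_assignments(vec, annot)
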