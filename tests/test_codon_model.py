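"""Rate matrix, transition probabilities, pruning likelihood, ML fitting."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from protsel import codon_model as cm
from protsel import synthetic_data as sd
from protsel.seqio import CODONS, CodonAlignment
from protsel.trees import Phylogeny


class TestRateMatrix:
    def test_uniform_world_all_rates_equal(self, freqs_uniform):
        spec = cm.CodonModelSpec(1.0, freqs_uniform, 1.0)
        Q = cm.build_rate_matrix(spec, 1.0)
        off = Q[~np.eye(61, dtype=bool)]
        permitted = off[off > 0]
        assert np.allclose(permitted, permitted[0])
        assert np.isclose(-(freqs_uniform @ np.diag(Q)), 1.0)

    def test_detailed_balance(self, freqs_skewed):
        spec = cm.CodonModelSpec(3.1, freqs_skewed, 0.7)
        Q = cm.build_rate_matrix(spec, 0.7)
        flux = freqs_skewed[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-15

    @pytest.mark.parametrize("kappa,omega", [(0.5, 0.1), (2.0, 1.0), (8.0, 4.0)])
    def test_rows_sum_to_zero(self, freqs_skewed, kappa, omega):
        spec = cm.CodonModelSpec(kappa, freqs_skewed, omega)
        Q = cm.build_rate_matrix(spec, omega)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_multi_nucleotide_changes_forbidden(self, freqs_uniform):
        spec = cm.CodonModelSpec(2.0, freqs_uniform, 1.0)
        Q = cm.build_rate_matrix(spec, 1.0)
        for i, j in itertools.product(range(61), repeat=2):
            if i == j:
                continue
            ndiff = sum(a != b for a, b in zip(CODONS[i], CODONS[j]))
            if ndiff > 1:
                assert Q[i, j] == 0.0


class TestTransitionProbabilities:
    def test_t_zero_is_identity(self, freqs_skewed):
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        Q = cm.build_rate_matrix(spec, 0.5)
        assert np.allclose(cm.transition_probabilities(Q, 0.0), np.eye(61))

    def test_ergodic_limit_is_pi(self, freqs_skewed):
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        Q = cm.build_rate_matrix(spec, 0.5)
        P = cm.transition_probabilities(Q, 500.0)
        assert np.abs(P - freqs_skewed[None, :]).max() < 1e-8

    def test_semigroup_property(self, freqs_skewed):
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        Q = cm.build_rate_matrix(spec, 0.5)
        P1 = cm.transition_probabilities(Q, 0.17)
        P2 = cm.transition_probabilities(Q, 0.34)
        assert np.abs(P1 @ P1 - P2).max() < 1e-10

    def test_negative_or_nonfinite_t_rejected(self, freqs_uniform):
        spec = cm.CodonModelSpec(2.0, freqs_uniform, 1.0)
        Q = cm.build_rate_matrix(spec, 1.0)
        for bad in (-0.1, np.nan, np.inf):
            with pytest.raises(ValueError):
                cm.transition_probabilities(Q, bad)

    def test_eigendecomposition_matches_expm(self, freqs_skewed):
        Q = cm._rate_matrix(2.7, freqs_skewed, 1.8)
        eg = cm._EigGenerator(2.7, freqs_skewed, 1.8)
        assert np.abs(eg.P(0.33) - expm(Q * 0.33)).max() < 1e-12


class TestLikelihood:
    def test_single_taxon_is_log_pi(self, freqs_skewed):
        tree = Phylogeny.from_newick("(A:0.0);")
        aln = CodonAlignment(["A"], ["ATGAAACGT"])
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        expected = sum(
            np.log(freqs_skewed[CODONS.index(c)]) for c in ("ATG", "AAA", "CGT")
        )
        assert np.isclose(cm.log_likelihood(aln, tree, spec), expected)

    def test_pruning_equals_enumeration(
        self, triplet_tree, toy_alignment, freqs_skewed
    ):
        """Brute-force sum over all 61^2 internal-state assignments."""
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        lnl = cm.log_likelihood(toy_alignment, triplet_tree, spec)
        Q = cm.build_rate_matrix(spec, 0.5)
        PA, PB = expm(Q * 0.1), expm(Q * 0.2)
        PN, PC = expm(Q * 0.15), expm(Q * 0.3)
        codes = toy_alignment.codes
        brute = 0.0
        for s in range(codes.shape[1]):
            a, b, c = codes[:, s]
            lik = 0.0
            for root in range(61):
                inner = PN[root] @ (PA[:, a] * PB[:, b])
                lik += freqs_skewed[root] * inner * PC[root, c]
            brute += np.log(lik)
        assert abs(lnl - brute) < 1e-10

    def test_duplicated_columns_double_lnl(self, triplet_tree, toy_alignment,
                                           freqs_skewed):
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        doubled = CodonAlignment(
            toy_alignment.taxa, [s + s for s in toy_alignment.sequences]
        )
        assert np.isclose(
            cm.log_likelihood(doubled, triplet_tree, spec),
            2 * cm.log_likelihood(toy_alignment, triplet_tree, spec),
        )

    def test_taxon_order_invariance(self, triplet_tree, toy_alignment,
                                    freqs_skewed):
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        shuffled = CodonAlignment(
            [toy_alignment.taxa[i] for i in (2, 0, 1)],
            [toy_alignment.sequences[i] for i in (2, 0, 1)],
        )
        assert np.isclose(
            cm.log_likelihood(shuffled, triplet_tree, spec),
            cm.log_likelihood(toy_alignment, triplet_tree, spec),
        )

    def test_reroot_invariance(self, toy_alignment, freqs_skewed):
        """Sliding the root along a branch leaves lnL unchanged."""
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        t1 = Phylogeny.from_newick("((A:0.1,B:0.2):0.1,C:0.2);")
        t2 = Phylogeny.from_newick("((A:0.1,B:0.2):0.05,C:0.25);")
        assert np.isclose(
            cm.log_likelihood(toy_alignment, t1, spec),
            cm.log_likelihood(toy_alignment, t2, spec),
        )

    def test_missing_data_sums_over_codons(self, triplet_tree, freqs_skewed):
        """A fully missing column contributes lnL 0 (probability 1)."""
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        base = CodonAlignment(["A", "B", "C"], ["ATG", "ATG", "ATG"])
        gapped = CodonAlignment(
            ["A", "B", "C"], ["ATG---", "ATG---", "ATG---"]
        )
        assert np.isclose(
            cm.log_likelihood(gapped, triplet_tree, spec),
            cm.log_likelihood(base, triplet_tree, spec),
        )

    def test_taxon_mismatch_rejected(self, triplet_tree, freqs_uniform):
        spec = cm.CodonModelSpec(2.0, freqs_uniform, 1.0)
        aln = CodonAlignment(["A", "B", "Z"], ["ATG", "ATG", "ATG"])
        with pytest.raises(ValueError):
            cm.log_likelihood(aln, triplet_tree, spec)


class TestFrequencies:
    def test_equal(self):
        aln = CodonAlignment(["x"], ["ATGAAA"])
        f = cm.codon_frequencies(aln, "equal")
        assert np.allclose(f, 1 / 61)

    def test_f3x4_sums_to_one_and_positive(self, m0_sim):
        aln, _, _ = m0_sim
        for model in ("F1X4", "F3X4", "F61"):
            f = cm.codon_frequencies(aln, model)
            assert np.isclose(f.sum(), 1.0) and f.min() > 0

    def test_unknown_model_rejected(self, m0_sim):
        with pytest.raises(ValueError):
            cm.codon_frequencies(m0_sim[0], "F99")


class TestFit:
    def test_m0_recovers_omega_and_kappa(self, quartet_tree, m0_sim):
        """Parameter recovery within 10% at Lc=2000 (simulation truth)."""
        aln, truth, _ = m0_sim
        r = cm.fit(
            aln, quartet_tree, "M0", optimize_branch_lengths=True, n_starts=1
        )
        assert abs(r.params["omega"] - 0.5) / 0.5 < 0.10
        assert abs(r.spec.kappa - 2.0) / 2.0 < 0.10
        # branch lengths too: compare sorted non-root lengths
        est = np.sort(r.branch_lengths[r.branch_lengths > 0])
        true = np.sort(quartet_tree.lengths[quartet_tree.lengths > 0])
        assert np.abs(est - true).max() / true.max() < 0.10
        assert r.converged

    def test_pinned_omega_never_beats_free(self, quartet_tree, m0_sim):
        aln, _, _ = m0_sim
        free = cm.fit(aln, quartet_tree, "M0",
                      optimize_branch_lengths=False, n_starts=1)
        pinned = cm.fit(aln, quartet_tree, "M0", fixed={"omega": 1.0},
                        optimize_branch_lengths=False, n_starts=1)
        assert pinned.lnL <= free.lnL + 1e-6
        assert pinned.n_params == free.n_params - 1

    def test_multistart_stability(self, quartet_tree, m0_sim):
        aln, _, _ = m0_sim
        fits = [
            cm.fit(aln, quartet_tree, "M0", optimize_branch_lengths=False,
                   n_starts=1, seed=s)
            for s in (0, 1, 2)
        ]
        lnls = [f.lnL for f in fits]
        assert max(lnls) - min(lnls) < 1e-4

    def test_aic_frequency_choice_runs(self, quartet_tree, m0_sim):
        aln, _, _ = m0_sim
        best = cm.choose_frequency_model(
            aln, quartet_tree, candidates=("equal", "F3X4"),
            optimize_branch_lengths=False, n_starts=1,
        )
        # data were simulated under skewed frequencies; equal should lose
        assert best == "F3X4"


class TestBranchExpectedSubs:
    def test_neutral_equality(self, freqs_skewed):
        spec = cm.CodonModelSpec(3.7, freqs_skewed, 1.0)
        dN, dS = cm.branch_expected_subs(spec, 1.0, 0.42)
        assert np.isclose(dN, dS) and np.isclose(dN, 0.42)

    def test_zero_branch(self, freqs_uniform):
        spec = cm.CodonModelSpec(2.0, freqs_uniform, 0.5)
        assert cm.branch_expected_subs(spec, 0.5, 0.0) == (0.0, 0.0)

    def test_ratio_reflects_omega(self, freqs_skewed):
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 2.0)
        dN, dS = cm.branch_expected_subs(spec, 2.0, 0.3)
        assert dN / dS > 1.0
        dN2, dS2 = cm.branch_expected_subs(spec, 0.2, 0.3)
        assert dN2 / dS2 < 1.0

    def test_realized_counts_match_expectation(self, freqs_skewed):
        """Gillespie-counted events on a long branch agree with the
        flux-partition expectations within 3 standard errors."""
        tree = Phylogeny.from_newick("(A:2.0,B:0.0);")
        spec = cm.CodonModelSpec(2.0, freqs_skewed, 0.5)
        n = 600
        aln, truth = sd.simulate_codon_alignment(
            tree, spec, n, seed=23, gillespie=True
        )
        counts = truth.realized_counts["A"]
        rho_n, rho_s = cm._flux_fractions(2.0, freqs_skewed, 0.5)
        # branch length 2.0 = expected substitutions per codon
        exp_total = 2.0 * n
        exp_n, exp_s = exp_total * rho_n, exp_total * rho_s
        for got, expected in [(counts["nonsyn"], exp_n), (counts["syn"], exp_s)]:
            assert abs(got - expected) < 3 * np.sqrt(expected)
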