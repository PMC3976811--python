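import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from wrkytools.selection import (
    CODONS,
    CodonAlignment,
    CodonLikelihood,
    LrtResult,
    backtranslate,
    beta_bin_means,
    fit_site_model,
    gy94_Q,
    lrt,
    model_categories,
    positive_sites,
    selection_report,
    significance_stars,
)
from wrkytools.synthetic_data import simulate_codon_alignment
from wrkytools.tree import parse_newick

RNG = np.random.default_rng(0)
PI = RNG.dirichlet(np.ones(61))


@pytest.fixture(scope="module")
def small_tree():
    return parse_newick(
        "((t1:0.15,t2:0.15):0.1,(t3:0.15,t4:0.15):0.1,(t5:0.15,t6:0.2):0.05);"
    )


@pytest.fixture(scope="module")
def mixture_fits(small_tree):
    """M0/M3/M7/M8 fits on one small simulated dataset (shared: fits are
    the expensive part of this module)."""
    aln, _ = simulate_codon_alignment(
        small_tree, kappa=2.0, omega_mixture=[(0.8, 0.2), (0.2, 1.0)],
        n_codons=120, seed=4,
    )
    m0 = fit_site_model(aln, small_tree, "M0")
    m3 = fit_site_model(aln, small_tree, "M3", null_fit=m0)
    m7 = fit_site_model(aln, small_tree, "M7", null_fit=m0)
    m8 = fit_site_model(aln, small_tree, "M8", null_fit=m7)
    return {"M0": m0, "M3": m3, "M7": m7, "M8": m8}


class TestBacktranslate:
    def test_basic_expansion(self):
        aln = backtranslate([("a", "M-K"), ("b", "MGK")],
                            {"a": "ATGAAA", "b": "ATGGGGAAA"})
        assert dict(aln.codon_strings()) == {"a": "ATG---AAA", "b": "ATGGGGAAA"}

    def test_terminal_stop_tolerated(self):
        aln = backtranslate([("a", "MK")], {"a": "ATGAAATAA"})
        assert dict(aln.codon_strings()) == {"a": "ATGAAA"}

    def test_mismatch_names_taxon_and_position(self):
        with pytest.raises(ValueError, match="b.*position 1"):
            backtranslate([("a", "MK"), ("b", "MW")],
                          {"a": "ATGAAA", "b": "ATGAAA"})

    def test_round_trip_translation(self):
        rng = np.random.default_rng(5)
        taxa = {}
        msa = []
        for name in ("x", "y", "z"):
            codons = [CODONS[i] for i in rng.integers(0, 61, size=25)]
            from wrkytools.selection import CODON_AA

            protein = "".join(CODON_AA[c] for c in codons)
            taxa[name] = "".join(codons)
            msa.append((name, protein))
        aln = backtranslate(msa, taxa)
        assert aln.translate() == msa


class TestRateMatrix:
    def test_rows_sum_to_zero_and_mean_rate_one(self):
        Q = gy94_Q(2.0, 0.5, PI)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -(PI * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_detailed_balance(self):
        Q = gy94_Q(3.0, 0.2, PI)
        flux = PI[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_uniform_neutral_rates_all_equal(self):
        pi = np.full(61, 1 / 61)
        Q = gy94_Q(1.0, 1.0, pi)
        off = Q[~np.eye(61, dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0])

    def test_multi_nucleotide_changes_forbidden(self):
        Q = gy94_Q(2.0, 1.0, PI)
        for i, ci in enumerate(CODONS[:10]):
            for j, cj in enumerate(CODONS):
                ndiff = sum(x != y for x, y in zip(ci, cj))
                if ndiff > 1:
                    assert Q[i, j] == 0.0

    def test_invalid_simplex_raises(self):
        with pytest.raises(ValueError):
            gy94_Q(2.0, 0.5, np.ones(61))


class TestLikelihood:
    def test_two_taxon_one_codon_matches_expm(self):
        aln = CodonAlignment(["a", "b"],
                             np.array([[CODONS.index("ATG")],
                                       [CODONS.index("ATA")]]))
        tree = parse_newick("(a:0.1,b:0.2);")
        eng = CodonLikelihood(aln, tree, codon_freqs=PI)
        lnl = eng.log_likelihood(2.0, [(1.0, 0.5)])
        P = expm(gy94_Q(2.0, 0.5, PI) * 0.3)
        want = np.log(PI[CODONS.index("ATG")]
                      * P[CODONS.index("ATG"), CODONS.index("ATA")])
        assert lnl == pytest.approx(want, abs=1e-8)

    def test_three_taxon_two_codon_matches_expm(self):
        aln = CodonAlignment(["a", "b", "c"], np.array([[1, 5], [2, 5], [1, 7]]))
        tree = parse_newick("(a:0.1,b:0.2,c:0.15);")
        eng = CodonLikelihood(aln, tree, codon_freqs=PI)
        lnl = eng.log_likelihood(1.7, [(1.0, 0.4)])
        Q = gy94_Q(1.7, 0.4, PI)
        Ps = [expm(Q * t) for t in (0.1, 0.2, 0.15)]
        want = 0.0
        for site in range(2):
            states = aln.codon_indices[:, site]
            want += np.log(sum(
                PI[r] * Ps[0][r, states[0]] * Ps[1][r, states[1]]
                * Ps[2][r, states[2]]
                for r in range(61)
            ))
        assert lnl == pytest.approx(want, abs=1e-8)

    def test_zero_length_star_tree_closed_form(self):
        idx = [CODONS.index(c) for c in ("ATG", "AAA", "TGG")]
        aln = CodonAlignment(["a", "b", "c"],
                             np.array([idx, idx, idx]))
        tree = parse_newick("(a:0,b:0,c:0);")
        eng = CodonLikelihood(aln, tree, codon_freqs=PI)
        lnl = eng.log_likelihood(2.0, [(1.0, 0.3)])
        assert lnl == pytest.approx(sum(np.log(PI[i]) for i in idx), abs=1e-10)

    def test_rerooting_invariance(self):
        aln = CodonAlignment(
            ["a", "b", "c", "d"],
            np.array([[1, 5, 9], [2, 5, 9], [1, 7, 11], [3, 7, 11]]),
        )
        t1 = parse_newick("((a:0.1,b:0.2):0.05,c:0.15,d:0.3);")
        t2 = parse_newick("((c:0.15,d:0.3):0.05,a:0.1,b:0.2);")
        l1 = CodonLikelihood(aln, t1, codon_freqs=PI).log_likelihood(2.0, [(1.0, 0.4)])
        l2 = CodonLikelihood(aln, t2, codon_freqs=PI).log_likelihood(2.0, [(1.0, 0.4)])
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_gaps_treated_as_missing(self):
        aln = CodonAlignment(["a", "b"], np.array([[1], [-1]]))
        tree = parse_newick("(a:0.1,b:0.1);")
        eng = CodonLikelihood(aln, tree, codon_freqs=PI)
        assert eng.log_likelihood(2.0, [(1.0, 1.0)]) == pytest.approx(
            np.log(PI[1]), abs=1e-10
        )

    def test_taxon_mismatch_raises(self):
        aln = CodonAlignment(["a", "b"], np.array([[1], [2]]))
        tree = parse_newick("(a:0.1,c:0.1);")
        with pytest.raises(ValueError, match="match"):
            CodonLikelihood(aln, tree)


class TestBetaDiscretisation:
    def test_equal_probability_bin_means(self):
        means = beta_bin_means(2.0, 5.0, k=10)
        assert len(means) == 10
        assert np.all(np.diff(means) > 0)
        # overall mean of bin means = distribution mean
        assert means.mean() == pytest.approx(2.0 / 7.0, rel=1e-6)

    def test_m8_weights_sum_to_one(self):
        cats = model_categories(
            "M8", {"p": 1.0, "q": 2.0, "p0": 0.8, "omega_s": 3.0}
        )
        assert sum(w for w, _ in cats) == pytest.approx(1.0)
        assert cats[-1][1] == 3.0


class TestModelFits:
    def test_m0_parameter_recovery(self, small_tree):
        aln, _ = simulate_codon_alignment(
            small_tree, kappa=2.0, omega_mixture=[(1.0, 0.3)],
            n_codons=300, seed=21,
        )
        fit = fit_site_model(aln, small_tree, "M0")
        assert 0.2 <= fit.params["omega"] <= 0.4
        assert 1.4 <= fit.kappa <= 2.8
        assert fit.converged

    def test_nesting_inequalities(self, mixture_fits):
        assert mixture_fits["M3"].lnl >= mixture_fits["M0"].lnl - 1e-6
        assert mixture_fits["M8"].lnl >= mixture_fits["M7"].lnl - 1e-6

    def test_identical_sequences_flagged(self):
        idx = [[1, 5, 9]] * 3
        aln = CodonAlignment(["a", "b", "c"], np.array(idx))
        tree = parse_newick("(a:0.1,b:0.1,c:0.1);")
        fit = fit_site_model(aln, tree, "M0", n_starts=1)
        assert "omega_unidentifiable_zero_tree_length" in fit.flags

    def test_posteriors_normalised(self, mixture_fits):
        post = mixture_fits["M8"].site_posteriors
        assert np.allclose(post.sum(axis=1), 1.0)
        assert (post >= 0).all()


class TestLrt:
    def test_reported_statistic_is_significant(self):
        # a 2*dlnL of 67.57 on 4 df is far beyond the 1% point (13.28)
        assert stats.chi2.ppf(0.99, 4) == pytest.approx(13.2767, abs=1e-3)
        p = float(stats.chi2.sf(67.57, 4))
        assert p < 0.01
        assert significance_stars(p) == "**"

    def test_zero_statistic_p_one(self, mixture_fits):
        m0 = mixture_fits["M0"]
        res = lrt(m0, mixture_fits["M3"])
        assert isinstance(res, LrtResult)
        same = lrt(m0, m0.__class__(**{**m0.__dict__, "model": "M3"}))
        assert same.stat == 0.0 and same.p_value == 1.0

    def test_wrong_pairing_raises(self, mixture_fits):
        with pytest.raises(ValueError):
            lrt(mixture_fits["M0"], mixture_fits["M8"])
        with pytest.raises(ValueError):
            lrt(mixture_fits["M0"], mixture_fits["M3"], df=2)

    def test_null_calibration_scaled_down(self):
        """Fitting M3 to M0-simulated data rejects at ~nominal rate or less
        (boundary conditions make the chi-square LRT conservative)."""
        tree = parse_newick("((a:0.2,b:0.2):0.1,c:0.2,d:0.3);")
        rejections = 0
        n_reps = 30
        for rep in range(n_reps):
            aln, _ = simulate_codon_alignment(
                tree, kappa=2.0, omega_mixture=[(1.0, 0.4)],
                n_codons=40, seed=1000 + rep,
            )
            m0 = fit_site_model(aln, tree, "M0", n_starts=1)
            m3 = fit_site_model(aln, tree, "M3", null_fit=m0)
            if lrt(m0, m3).p_value < 0.05 :
                rejections += 1
        # binomial(30, 0.05) upper tail: P(X >= 6) < 0.0003
        assert rejections <= 5


class TestPositiveSites:
    def test_purifying_simulation_empty(self, small_tree):
        aln, _ = simulate_codon_alignment(
            small_tree, kappa=2.0, omega_mixture=[(1.0, 0.2)],
            n_codons=100, seed=33,
        )
        m7 = fit_site_model(aln, small_tree, "M7")
        m8 = fit_site_model(aln, small_tree, "M8", null_fit=m7)
        assert positive_sites(m8) == []

    def test_planted_sites_recovered_strong_signal(self):
        pend, inner = 1.2, 0.6
        tree = parse_newick(
            f"(((t1:{pend},t2:{pend}):{inner},(t3:{pend},t4:{pend}):{inner})"
            f":{inner / 2},(t5:{pend},t6:{pend}):{inner},"
            f"(t7:{pend},t8:{pend}):{inner / 2});"
        )
        aln, classes = simulate_codon_alignment(
            tree, kappa=2.0, omega_mixture=[(0.9, 0.1), (0.1, 8.0)],
            n_codons=300, seed=9,
        )
        m7 = fit_site_model(aln, tree, "M7")
        m8 = fit_site_model(aln, tree, "M8", null_fit=m7)
        called = set(positive_sites(m8))
        planted = set(np.nonzero(classes == 1)[0])
        assert len(called & planted) >= len(planted) / 2
        neutral = set(range(aln.n_sites)) - planted
        assert len(called - planted) <= 0.05 * len(neutral)


class TestReport:
    def test_all_purifying_row(self, mixture_fits):
        lrts = {
            "M0_M3": lrt(mixture_fits["M0"], mixture_fits["M3"]),
            "M7_M8": lrt(mixture_fits["M7"], mixture_fits["M8"]),
        }
        df = selection_report(
            [{"name": "toy", "fits": mixture_fits, "lrts": lrts}]
        )
        row = df.iloc[0]
        assert row["omega_M0"] < 1.0
        assert row["n_positive_sites"] == 0
        assert row["2dlnL_M8_vs_M7"] >= 0.0

    def test_empty_input_empty_table(self):
        assert selection_report([]).empty

    def test_star_thresholds(self):
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.011) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.2) == ""


class TestSimulatorContracts:
    def test_omega_zero_no_nonsynonymous_changes(self, small_tree):
        from wrkytools.selection import CODON_AA

        aln, _ = simulate_codon_alignment(
            small_tree, kappa=2.0, omega_mixture=[(1.0, 0.0)],
            n_codons=150, seed=2,
        )
        proteins = {
            t: "".join(CODON_AA[CODONS[i]] for i in row)
            for t, row in zip(aln.taxa, aln.codon_indices)
        }
        assert len(set(proteins.values())) == 1

    def test_zero_branch_lengths_identical_sequences(self):
        tree = parse_newick("(a:0,b:0,c:0);")
        aln, _ = simulate_codon_alignment(
            tree, kappa=2.0, omega_mixture=[(1.0, 0.5)], n_codons=60, seed=3
        )
        rows = aln.codon_indices
        assert (rows == rows[0]).all()

    def test_pairwise_substitutions_match_expectation(self):
        t = 0.5
        tree = parse_newick(f"(a:{t},b:0);")
        kappa, omega = 2.0, 0.5
        n = 1000
        aln, _ = simulate_codon_alignment(
            tree, kappa=kappa, omega_mixture=[(1.0, omega)], n_codons=n, seed=8
        )
        pi = np.full(61, 1 / 61)
        P = expm(gy94_Q(kappa, omega, pi) * t)
        p_diff = 1.0 - (pi * np.diag(P)).sum()
        observed = (aln.codon_indices[0] != aln.codon_indices[1]).mean()
        se = np.sqrt(p_diff * (1 - p_diff) / n)
        assert abs(observed - p_diff) < 4 * se
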