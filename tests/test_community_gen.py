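"""Community generator: margins, niches, suitability, assignment, swapping."""

import itertools

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chisquare, kstest, spearmanr

from nichesim.community_gen import (
    CommunitySpec,
    DistributionSpec,
    InfeasibleMarginsError,
    MarginVectors,
    NicheRule,
    assign_niches,
    build_rank_abundance,
    build_richness,
    default_community_spec,
    gale_ryser_feasible,
    generate_community,
    initial_assignment,
    log_suitability_matrix,
    read_community,
    reconcile_margins,
    refine_by_swapping,
    suitability,
    swap_objective,
    write_community,
)

# ---------------------------------------------------------------------------
# marginal distributions


class TestRankAbundance:
    def test_log_linear_is_linear_in_log_abundance(self, rng):
        ab = build_rank_abundance(
            DistributionSpec("log_linear", {"max_abundance": 500, "decay": 0.006}),
            1000, 1000, rng,
        )
        assert len(ab) == 1000 and ab.min() >= 1 and ab.max() <= 1000
        # before rounding bites (abundance >= 20), log-abundance declines
        # linearly with rank at slope -decay
        big = ab >= 20
        slope = np.polyfit(np.arange(1000)[big], np.log(ab[big]), 1)[0]
        assert slope == pytest.approx(-0.006, rel=0.02)

    def test_single_species_degenerate(self, rng):
        ab = build_rank_abundance(
            DistributionSpec("log_linear", {"max_abundance": 10, "decay": 1.0}),
            1, 50, rng,
        )
        assert ab.shape == (1,) and 1 <= ab[0] <= 50

    def test_log_normal_matches_sampling_distribution(self):
        # ECDF of the generated abundances against the closed-form CDF of a
        # round-half-up, clamped log-normal: the KS distance must be small
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        mu, sigma = 2.0, 0.8
        n_sites = 1000
        ab = build_rank_abundance(
            DistributionSpec("log_normal", {"mu": mu, "sigma": sigma}),
            1000, n_sites, rng,
        )
        support = np.arange(1, n_sites + 1)
        cdf = norm.cdf((np.log(support + 0.5) - mu) / sigma)
        cdf[-1] = 1.0  # clamp absorbs the upper tail
        ecdf = np.searchsorted(np.sort(ab), support, side="right") / len(ab)
        # one-sample KS critical value at alpha = 0.001 for n = 1000
        d_crit = np.sqrt(np.log(2 / 0.001) / (2 * len(ab)))
        assert np.abs(ecdf - cdf).max() < d_crit

    def test_empirical_table_only_draws_listed_values(self, rng):
        spec = DistributionSpec(
            "empirical_table", {"values": [1, 5, 20], "frequencies": [10, 3, 1]}
        )
        ab = build_rank_abundance(spec, 200, 100, rng)
        assert set(np.unique(ab)) <= {1, 5, 20}

    def test_empirical_table_from_file(self, rng, tmp_path):
        path = tmp_path / "table.txt"
        path.write_text("2 7\n9 1\n")
        ab = build_rank_abundance(
            DistributionSpec("empirical_table", {"path": str(path)}), 100, 50, rng
        )
        assert set(np.unique(ab)) <= {2, 9}

    def test_infeasible_spec_rejected(self, rng):
        with pytest.raises(ValueError, match="infeasible"):
            build_rank_abundance(
                DistributionSpec("log_linear", {"max_abundance": 5000, "decay": 1e-6}),
                1000, 100, rng,
            )

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            DistributionSpec("zipf", {})


class TestRichness:
    def test_log_linear_frequencies_decline_log_linearly(self, rng):
        ri = build_richness(
            DistributionSpec("log_linear", {"rate": 0.1, "max_richness": 60}),
            20_000, 1000, rng,
        )
        assert ri.min() >= 0 and ri.max() <= 60
        counts = np.bincount(ri, minlength=41)[:41]
        slope = np.polyfit(np.arange(41), np.log(counts), 1)[0]
        assert slope == pytest.approx(-0.1, abs=0.01)

    def test_point_mass_table_gives_constant_vector(self, rng):
        ri = build_richness(
            DistributionSpec("empirical_table", {"values": [7], "frequencies": [1]}),
            30, 100, rng,
        )
        assert np.all(ri == 7)

    def test_sites_are_exchangeable(self, rng):
        ri = build_richness(
            DistributionSpec("log_linear", {"rate": 0.2, "max_richness": 30}),
            500, 100, rng,
        )
        perm = rng.permutation(ri)
        assert np.array_equal(np.bincount(ri), np.bincount(perm))


class TestReconcileMargins:
    def test_equal_sums_returned_unchanged(self, rng):
        ab = np.array([3, 2, 1])
        ri = np.array([2, 2, 1, 1])
        m = reconcile_margins(ab, ri, 4, 3, rng)
        assert np.array_equal(m.abundance, ab)
        assert np.array_equal(m.richness, ri)

    def test_richness_total_adjusted_by_units(self, rng):
        ab = np.full(50, 100)  # total 5000
        ri = np.full(100, 49)  # total 4900 -> +100 needed
        m = reconcile_margins(ab, ri, 100, 50, rng)
        assert m.richness.sum() == 5000
        assert np.abs(m.richness - 49).sum() == 100  # unit increments only
        assert np.array_equal(m.abundance, ab)

    def test_random_feasible_margins_are_realizable(self):
        # brute-force realization check: every reconciled margin pair passes
        # Gale-Ryser and is actually realized by initial_assignment
        rng = np.random.default_rng(5)
        for _ in range(100):
            n_sp, n_si = rng.integers(2, 8, size=2)
            ab = rng.integers(1, n_si + 1, size=n_sp)
            ri = rng.integers(0, n_sp + 1, size=n_si)
            try:
                m = reconcile_margins(ab, ri, n_si, n_sp, rng)
            except InfeasibleMarginsError:
                continue
            P = initial_assignment(m, rng)
            assert np.array_equal(P.sum(axis=1), m.abundance)
            assert np.array_equal(P.sum(axis=0), m.richness)

    def test_gale_ryser_rejects_impossible_margins(self, rng):
        # two species needing 3 sites each, but only one site can host 2 species
        ok, k = gale_ryser_feasible(np.array([3, 3]), np.array([2, 1, 1, 1, 1]), 5)
        assert ok
        ok, k = gale_ryser_feasible(np.array([3, 3]), np.array([6]), 5)
        assert not ok


class TestNiches:
    def test_width_monotone_in_abundance(self, rng):
        spec = default_community_spec(1000, 2, seed=0)
        margins = MarginVectors(np.array([500, 10]), np.array([]))
        _, widths = assign_niches(margins, spec, rng)
        assert widths[0] >= widths[1]

    def test_zero_slope_gives_equal_widths(self, rng):
        spec = CommunitySpec(
            n_sites=100, n_species=3,
            rank_abundance=DistributionSpec("log_linear", {}),
            richness_pattern=DistributionSpec("log_linear", {}),
            niche=NicheRule(width_intercept=0.3, width_slope=0.0),
        )
        margins = MarginVectors(np.array([50, 10, 1]), np.array([]))
        _, widths = assign_niches(margins, spec, rng)
        assert np.allclose(widths, 0.3)

    def test_optima_uniform_over_range(self):
        rng = np.random.default_rng(0)
        spec = default_community_spec(100, 5000, seed=0)
        margins = MarginVectors(np.ones(5000, dtype=int), np.array([]))
        optima, _ = assign_niches(margins, spec, rng)
        assert kstest(optima, "uniform").pvalue > 0.01


class TestSuitability:
    def test_maximum_at_optimum(self):
        assert suitability(0.4, 0.4, 0.1, 2.0) == pytest.approx(expit(2.0))

    def test_symmetry_about_optimum(self):
        for d in (0.01, 0.1, 0.3):
            assert suitability(0.5 + d, 0.5, 0.08, 1.5) == pytest.approx(
                suitability(0.5 - d, 0.5, 0.08, 1.5)
            )

    def test_closed_form_one_width_from_optimum(self):
        # h=0 and |e-c| = w gives expit(-1)
        assert suitability(0.6, 0.5, 0.1, 0.0) == pytest.approx(0.26894142, abs=1e-6)

    def test_unimodal_in_environment(self):
        e = np.linspace(0, 1, 201)
        s = suitability(e, 0.37, 0.05, 2.0)
        diffs = np.sign(np.diff(s))
        switch = np.flatnonzero(np.diff(diffs) != 0)
        assert len(switch) <= 1  # rises then falls


class TestInitialAssignment:
    def test_forced_realization_all_ones_row(self, rng):
        m = MarginVectors(np.array([4]), np.array([1, 1, 1, 1]))
        P = initial_assignment(m, rng)
        assert np.all(P)

    def test_margins_exact_over_seeds(self):
        m = MarginVectors(np.array([3, 2, 2, 1]), np.array([2, 2, 2, 1, 1]))
        for seed in range(100):
            P = initial_assignment(m, np.random.default_rng(seed))
            assert np.array_equal(P.sum(axis=1), m.abundance)
            assert np.array_equal(P.sum(axis=0), m.richness)

    def test_all_realizations_reachable_and_roughly_uniform(self):
        # margins ab=[2,1], rich=[1,1,1] admit exactly 3 matrices; all must
        # occur with positive and comparable frequency over 1000 seeds
        m = MarginVectors(np.array([2, 1]), np.array([1, 1, 1]))
        counts: dict[bytes, int] = {}
        for seed in range(1000):
            P = initial_assignment(m, np.random.default_rng(seed))
            counts[P.tobytes()] = counts.get(P.tobytes(), 0) + 1
        assert len(counts) == 3
        assert chisquare(list(counts.values())).pvalue > 0.001


def _enumerate_margin_matrices(abundance, richness):
    """All binary matrices with the given margins (tiny instances only)."""
    n_sites = len(richness)
    rows = [
        list(itertools.combinations(range(n_sites), a)) for a in abundance
    ]
    for combo in itertools.product(*rows):
        P = np.zeros((len(abundance), n_sites), dtype=bool)
        for s, sites in enumerate(combo):
            P[s, list(sites)] = True
        if np.array_equal(P.sum(axis=0), richness):
            yield P


class TestRefineBySwapping:
    def test_margins_invariant_under_refinement(self, rng):
        m = MarginVectors(np.array([5, 3, 2, 2]), np.array([2, 2, 2, 2, 2, 2]))
        P = initial_assignment(m, rng)
        ls = np.log(rng.uniform(0.05, 0.95, size=P.shape))
        Q, _ = refine_by_swapping(P, ls, rng)
        assert np.array_equal(Q.sum(axis=1), m.abundance)
        assert np.array_equal(Q.sum(axis=0), m.richness)

    def test_objective_never_decreases(self, rng):
        for seed in range(50):
            r = np.random.default_rng(seed)
            m = MarginVectors(np.array([3, 2, 2, 1]), np.array([2, 2, 2, 1, 1]))
            P = initial_assignment(m, r)
            ls = np.log(r.uniform(0.05, 0.95, size=P.shape))
            Q, stats = refine_by_swapping(P, ls, r)
            assert swap_objective(Q, ls) >= swap_objective(P, ls) - 1e-9
            assert stats["objective_gain"] >= -1e-9

    def test_local_optimum_is_fixed_point(self, rng):
        # two species with optima at opposite gradient ends, already sorted:
        # no improving swap exists and the matrix is returned unchanged
        ls = log_suitability_matrix(
            np.linspace(0, 1, 4), np.array([0.0, 1.0]), np.array([0.2, 0.2]), 2.0
        )
        P = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=bool)
        Q, stats = refine_by_swapping(P, ls, rng)
        assert np.array_equal(P, Q)
        assert stats["n_accepted"] == 0

    def test_antisorted_species_end_at_their_optima(self, rng):
        # anti-sorted start; refinement must reach the global optimum found
        # by exhaustive search over all margin-preserving matrices
        env = np.linspace(0, 1, 4)
        ls = log_suitability_matrix(env, np.array([0.0, 1.0]), np.array([0.2, 0.2]), 2.0)
        P = np.array([[0, 0, 1, 1], [1, 1, 0, 0]], dtype=bool)
        Q, _ = refine_by_swapping(P, ls, rng)
        best = max(
            _enumerate_margin_matrices(P.sum(axis=1), P.sum(axis=0)),
            key=lambda M: swap_objective(M, ls),
        )
        assert swap_objective(Q, ls) == pytest.approx(swap_objective(best, ls))
        assert np.array_equal(Q, np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=bool))


class TestGenerateCommunity:
    def test_determinism(self):
        spec = default_community_spec(40, 30, seed=77)
        a = generate_community(spec)
        b = generate_community(spec)
        assert np.array_equal(a.presence, b.presence)
        assert np.array_equal(a.optima, b.optima)

    def test_environment_linear_unit_interval(self, small_community):
        e = small_community.environment
        assert e[0] == 0.0 and e[-1] == 1.0
        assert np.allclose(np.diff(e), e[1] - e[0])

    def test_margins_exact(self, small_community):
        c = small_community
        assert np.array_equal(c.presence.sum(axis=1), c.margins.abundance)
        assert np.array_equal(c.presence.sum(axis=0), c.margins.richness)

    def test_refinement_creates_environmental_signal(self, small_community):
        """Occupied-site mean environment tracks each species' optimum, and
        more tightly than in the environment-blind initial assignment."""
        c = small_community
        rng = np.random.default_rng(0)
        P0 = initial_assignment(c.margins, rng)
        sel = c.margins.abundance < c.n_sites / 2

        def corr(P):
            occ = np.array([c.environment[P[s]].mean() for s in range(c.n_species)])
            return spearmanr(occ[sel], c.optima[sel]).statistic

        rho_refined = corr(c.presence)
        assert rho_refined > 0
        assert rho_refined > corr(P0)

    def test_roundtrip_serialization(self, small_community, tmp_path):
        write_community(small_community, tmp_path / "comm")
        back = read_community(tmp_path / "comm")
        assert np.array_equal(back.presence, small_community.presence)
        assert np.allclose(back.environment, small_community.environment)
        assert np.allclose(back.optima, small_community.optima)
        assert back.spec.n_sites == small_community.spec.n_sites
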