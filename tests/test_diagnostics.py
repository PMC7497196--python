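"""PSRF, Geweke, HDI and the ordered-z posterior-predictive check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matalloc.diagnostics import (blom_scores, gelman_rubin, geweke,
                                  gof_ordered_z, hdi, psrf_table)


def brute_force_hdi(draws, mass=0.90):
    """Independent oracle: exhaustive scan over all sorted windows."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    k = int(np.ceil(mass * n))
    best = None
    for start in range(n - k + 1):
        width = x[start + k - 1] - x[start]
        if best is None or width < best[0] - 1e-15:
            best = (width, x[start], x[start + k - 1])
    return best[1], best[2]


class TestGelmanRubin:
    def test_stationary_chains_near_one(self, rng):
        chains = rng.standard_normal((3, 5000))
        assert 1.0 <= gelman_rubin(chains) <= 1.05 or \
            gelman_rubin(chains) == pytest.approx(1.0, abs=0.05)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 2.0

    def test_constant_chains_flagged_not_raised(self):
        assert np.isnan(gelman_rubin(np.ones((3, 100))))

    def test_identical_chain_copies_degenerate(self, rng):
        one = rng.standard_normal(200)
        r = gelman_rubin(np.stack([one, one, one]))
        # between-chain variance collapses; value well below separation
        assert r == pytest.approx(1.0, abs=0.01)

    def test_psrf_table_pass_column(self, rng):
        table = psrf_table({"good": rng.standard_normal((3, 2000)),
                            "bad": np.stack([rng.normal(0, 1, 2000),
                                             rng.normal(8, 1, 2000),
                                             rng.normal(-8, 1, 2000)])})
        table = table.set_index("parameter")
        assert bool(table.loc["good", "pass"])
        assert not bool(table.loc["bad", "pass"])

    def test_rejects_short_or_single_chain(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((3, 5)))


class TestGeweke:
    def test_null_distribution_rarely_exceeds_three(self):
        rng = np.random.default_rng(0)
        z = np.array([geweke(rng.standard_normal(10_000)) for _ in range(100)])
        assert np.mean(np.abs(z) < 3) >= 0.99

    def test_linear_trend_detected(self):
        assert abs(geweke(np.linspace(0, 1, 10_000))) > 5

    def test_affine_invariance(self, rng):
        chain = rng.standard_normal(2000)
        assert geweke(3.7 * chain - 11.0) == pytest.approx(geweke(chain),
                                                           rel=1e-9)

    def test_constant_segment_flagged(self):
        chain = np.concatenate([np.zeros(500), np.random.default_rng(0)
                                .standard_normal(500)])
        assert np.isnan(geweke(chain))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke(np.arange(50.0))


class TestHdi:
    def test_evenly_spaced_uniform_tie_break(self):
        x = np.arange(100.0)
        interval = hdi(x, mass=0.90)
        # all 90-draw windows tie; the tie-break starts at the minimum
        assert interval.lower == 0.0
        assert interval.upper == 89.0
        assert np.sum((x >= interval.lower) & (x <= interval.upper)) == 90

    def test_matches_brute_force_scan(self, rng):
        for n in (20, 37, 50, 128, 200):
            for _ in range(5):
                draws = rng.standard_normal(n) ** 3  # skewed
                interval = hdi(draws, mass=0.90)
                lo, hi = brute_force_hdi(draws, mass=0.90)
                assert interval.lower == pytest.approx(lo)
                assert interval.upper == pytest.approx(hi)

    def test_symmetric_sample_close_to_central_interval(self, rng):
        draws = rng.standard_normal(200_000)
        interval = hdi(draws, mass=0.90)
        q05, q95 = np.quantile(draws, [0.05, 0.95])
        mc_se = 2 * (q95 - q05) / np.sqrt(len(draws) * 0.1)
        assert abs(interval.lower - q05) < 30 * mc_se
        assert abs(interval.upper - q95) < 30 * mc_se

    @given(st.integers(0, 2 ** 32 - 1), st.sampled_from([0.5, 0.8, 0.9, 0.95]))
    @settings(max_examples=40, deadline=None)
    def test_fraction_inside_at_least_mass(self, seed, mass):
        draws = np.random.default_rng(seed).exponential(size=73)
        interval = hdi(draws, mass=mass)
        inside = np.mean((draws >= interval.lower) & (draws <= interval.upper))
        assert inside >= mass

    def test_agrees_with_arviz_on_large_samples(self, rng):
        arviz = pytest.importorskip("arviz")
        draws = rng.gamma(3.0, size=50_000)
        ours = hdi(draws, mass=0.90)
        theirs = arviz.hdi(draws, hdi_prob=0.90)
        assert ours.lower == pytest.approx(theirs[0], abs=0.05)
        assert ours.upper == pytest.approx(theirs[1], abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hdi(np.arange(100.0), mass=1.5)
        with pytest.raises(ValueError):
            hdi(np.arange(10.0))


class TestGofOrderedZ:
    def _run(self, data_rng, check_rng, heavy_tails=False, n=60, s=300):
        mu_true = data_rng.normal(0, 1, n)
        if heavy_tails:
            y = mu_true + data_rng.standard_t(2, n)
        else:
            y = mu_true + data_rng.standard_normal(n)
        mu = np.tile(mu_true, (s, 1)) + 0.05 * check_rng.standard_normal((s, n))
        sigma = np.full(s, 1.0)
        return gof_ordered_z(y, mu, sigma, check_rng)

    def test_well_specified_p_values_central(self):
        hits = 0
        for seed in range(20):
            result = self._run(np.random.default_rng(seed),
                               np.random.default_rng(1000 + seed))
            if 0.05 <= result.p_value <= 0.95:
                hits += 1
        assert hits >= 18

    def test_heavy_tailed_misfit_detected(self):
        extreme = 0
        for seed in range(12):
            result = self._run(np.random.default_rng(seed),
                               np.random.default_rng(2000 + seed),
                               heavy_tails=True)
            if result.p_value < 0.05 or result.p_value > 0.95:
                extreme += 1
        assert extreme >= 7

    def test_zero_sigma_flagged_degenerate(self, rng):
        result = gof_ordered_z(np.zeros(20), np.zeros((5, 20)), np.zeros(5), rng)
        assert result.degenerate

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            gof_ordered_z(np.zeros(5), np.zeros((3, 5)), np.ones(3), rng)

    def test_blom_scores_symmetric(self):
        m = blom_scores(15)
        np.testing.assert_allclose(m, -m[::-1], atol=1e-12)
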