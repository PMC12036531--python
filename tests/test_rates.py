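import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pausekit import (
    PauseRateModel,
    build_count_table,
    fit_rate_model,
    group_mu_difference,
    hdi,
    nb_loglik,
    posterior_predictive_check,
)
from pausekit.rates import DifferenceSummary, GroupRatePosterior, sample_nb


def _nb_pmf_recursive(k_max, mu, beta):
    """Direct pmf by the forward recursion, independent of gammaln."""
    p = np.empty(k_max + 1)
    p[0] = (beta / (beta + mu)) ** beta
    for k in range(k_max):
        p[k + 1] = p[k] * (k + beta) / (k + 1) * (mu / (beta + mu))
    return p


def _sim_table(rng, spec):
    """CountTable rows for {group: (mu, beta, n)} with class 'all'."""
    rows = []
    for g, (mu, beta, n) in spec.items():
        counts = sample_nb(rng, mu, beta, n)
        for i, c in enumerate(counts):
            rows.append(
                {
                    "speaker_id": f"{g}-{i % 10}",
                    "group": g,
                    "moment": 0,
                    "fragment_id": i,
                    "pause_class": "all",
                    "count": int(c),
                    "silence_s": float(c) * 0.5,
                    "avg_pause_len_ms": 500.0,
                }
            )
    return pd.DataFrame(rows)


class TestNBLoglik:
    def test_geometric_special_case(self):
        assert nb_loglik([0], 1.0, 1.0) == pytest.approx(math.log(0.5))

    def test_matches_direct_pmf_summation(self):
        """100 random (counts, mu, beta) cases vs the recursion oracle."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            mu = rng.uniform(0.2, 15.0)
            beta = rng.uniform(0.3, 30.0)
            counts = rng.integers(0, 40, size=rng.integers(1, 12))
            pmf = _nb_pmf_recursive(int(counts.max()), mu, beta)
            expected = float(np.sum(np.log(pmf[counts])))
            assert nb_loglik(counts, mu, beta) == pytest.approx(expected, rel=1e-9)

    def test_example_counts(self):
        pmf = _nb_pmf_recursive(5, 4.0, 2.0)
        expected = math.log(pmf[3]) + math.log(pmf[5]) + math.log(pmf[2])
        assert nb_loglik([3, 5, 2], 4.0, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_poisson_limit(self):
        counts = np.array([0, 1, 2, 5, 9])
        target = float(stats.poisson.logpmf(counts, 3.0).sum())
        assert nb_loglik(counts, 3.0, 1e6) == pytest.approx(target, abs=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            nb_loglik([1.5], 1.0, 1.0)
        with pytest.raises(ValueError):
            nb_loglik([-1], 1.0, 1.0)
        with pytest.raises(ValueError):
            nb_loglik([1], -1.0, 1.0)


class TestHDI:
    def test_constant_samples(self):
        iv = hdi(np.full(50, 3.2))
        assert (iv.lower, iv.upper) == (3.2, 3.2)

    def test_1_to_100_window(self):
        iv = hdi(np.arange(1, 101, dtype=float), mass=0.89)
        assert iv.upper - iv.lower == pytest.approx(88.0)

    def test_standard_normal_endpoints(self):
        rng = np.random.default_rng(1)
        iv = hdi(rng.standard_normal(100_000), mass=0.89)
        z = stats.norm.ppf(0.5 + 0.89 / 2)
        assert iv.lower == pytest.approx(-z, abs=0.05)
        assert iv.upper == pytest.approx(z, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_window_scan(self, seed):
        """Implementation agrees with a brute-force scan of every window."""
        rng = np.random.default_rng(seed)
        x = np.sort(rng.gamma(2.0, 1.5, size=400))
        mass = 0.89
        m = math.ceil(mass * len(x))
        best = min(
            ((x[i + m - 1] - x[i], i) for i in range(len(x) - m + 1)),
        )
        iv = hdi(x, mass)
        assert iv.lower == pytest.approx(x[best[1]])
        assert iv.upper == pytest.approx(x[best[1] + m - 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_containment_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(size=777)
        iv = hdi(x, 0.89)
        frac = np.mean((x >= iv.lower) & (x <= iv.upper))
        assert frac >= 0.89

    def test_validation(self):
        with pytest.raises(ValueError):
            hdi(np.arange(5))
        with pytest.raises(ValueError):
            hdi(np.arange(100), mass=1.5)


class TestRateModel:
    def test_parameter_recovery(self):
        """Posterior mean of mu within 10% of the generating value."""
        rng = np.random.default_rng(10)
        table = _sim_table(rng, {"g1": (6.0, 8.0, 250), "g2": (6.0, 8.0, 250)})
        model = PauseRateModel(table, pause_class="all")
        post = model.fit(n_chains=2, n_iter=3000, seed=0)
        for g in ("g1", "g2"):
            assert post.mu[g].mean() == pytest.approx(6.0, rel=0.10)
        assert post.accept_rate > 0.1

    def test_identical_groups_difference_includes_zero(self):
        rng = np.random.default_rng(11)
        table = _sim_table(rng, {"g1": (5.0, 10.0, 150), "g2": (5.0, 10.0, 150)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=2500, seed=1)
        diff = DifferenceSummary.from_samples(post.mu["g1"] - post.mu["g2"])
        assert not diff.excludes_zero

    def test_group_vs_itself_zero_difference(self):
        rng = np.random.default_rng(12)
        table = _sim_table(rng, {"g1": (5.0, 10.0, 60), "g2": (8.0, 10.0, 60)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=1200, seed=2)
        diff = group_mu_difference(post, "g1", "g1")
        assert (diff.hdi.lower, diff.hdi.upper) == (0.0, 0.0)
        assert not diff.excludes_zero

    def test_separated_groups_exclude_zero(self):
        rng = np.random.default_rng(13)
        table = _sim_table(rng, {"g1": (2.0, 10.0, 150), "g2": (9.0, 10.0, 150)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=2500, seed=3)
        diff = group_mu_difference(post, "g1", "g2")
        assert diff.excludes_zero
        assert diff.hdi.upper < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_excludes_zero_flag_consistency(self, seed):
        rng = np.random.default_rng(seed)
        samples = rng.normal(rng.uniform(-1, 1), 0.5, size=(2, 500))
        diff = DifferenceSummary.from_samples(samples)
        inside = diff.hdi.lower <= 0.0 <= diff.hdi.upper
        assert diff.excludes_zero == (not inside)

    def test_unknown_group_raises(self):
        rng = np.random.default_rng(14)
        table = _sim_table(rng, {"g1": (5.0, 10.0, 40), "g2": (5.0, 10.0, 40)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=600, seed=0)
        with pytest.raises(KeyError):
            group_mu_difference(post, "g1", "nope")

    def test_diagnostics_reported(self):
        rng = np.random.default_rng(15)
        table = _sim_table(rng, {"g1": (5.0, 10.0, 120), "g2": (7.0, 10.0, 120)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=2000, seed=4)
        assert set(post.rhat) == {"mu[g1]", "mu[g2]", "beta"}
        assert all(np.isfinite(v) for v in post.rhat.values())
        assert all(v > 0 for v in post.ess.values())

    def test_covariate_terms_optional(self):
        rng = np.random.default_rng(16)
        table = _sim_table(rng, {"g1": (5.0, 10.0, 80), "g2": (7.0, 10.0, 80)})
        post = PauseRateModel(table, "all", include_covariates=True).fit(
            n_chains=2, n_iter=800, seed=5
        )
        assert set(post.coefs) == {"b_silence", "b_length", "b_interaction"}

    def test_validation(self):
        rng = np.random.default_rng(17)
        table = _sim_table(rng, {"g1": (5.0, 10.0, 40)})
        with pytest.raises(ValueError):
            PauseRateModel(table, "all")  # single group
        small = _sim_table(rng, {"g1": (5.0, 10.0, 5), "g2": (5.0, 10.0, 40)})
        with pytest.raises(ValueError):
            PauseRateModel(small, "all")  # too few fragments


class TestPosteriorPredictiveCheck:
    def test_self_consistency(self):
        """Data generated from the model itself scores a small TV distance."""
        rng = np.random.default_rng(20)
        table = _sim_table(rng, {"g1": (5.0, 8.0, 500), "g2": (5.0, 8.0, 500)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=2500, seed=6)
        ppc = posterior_predictive_check(post, table, seed=0)
        assert all(r.tv_distance <= 0.1 for r in ppc.values())

    def test_mismatched_model_scores_worse(self):
        """A dispersion-free (Poisson-like) posterior fits overdispersed
        counts worse than the fitted Gamma-Poisson posterior."""
        rng = np.random.default_rng(21)
        table = _sim_table(rng, {"g1": (6.0, 1.5, 300), "g2": (6.0, 1.5, 300)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=2500, seed=7)
        ppc_fit = posterior_predictive_check(post, table, seed=1)
        fake = GroupRatePosterior(
            pause_class="all",
            groups=post.groups,
            mu={g: np.full((1, 400), 6.0) for g in post.groups},
            beta=np.full((1, 400), 1e6),  # Poisson limit: variance collapses
            rhat={}, ess={}, accept_rate=1.0,
        )
        ppc_poisson = posterior_predictive_check(fake, table, seed=1)
        for g in post.groups:
            assert ppc_poisson[g].tv_distance > ppc_fit[g].tv_distance

    def test_empty_group_skipped_with_warning(self):
        rng = np.random.default_rng(22)
        table = _sim_table(rng, {"g1": (5.0, 8.0, 60), "g2": (5.0, 8.0, 60)})
        post = PauseRateModel(table, "all").fit(n_chains=2, n_iter=600, seed=8)
        reduced = table[table["group"] == "g1"]
        with pytest.warns(UserWarning, match="no fragments"):
            ppc = posterior_predictive_check(post, reduced, seed=2)
        assert set(ppc) == {"g1"}


class TestCountTable:
    def _pauses(self):
        return pd.DataFrame(
            {
                "speaker_id": ["s1", "s1", "s1", "s2"],
                "group": ["control"] * 3 + ["svPPA"],
                "moment": [0, 0, 0, 0],
                "fragment_id": [0, 0, 1, 0],
                "duration_ms": [100.0, 600.0, 300.0, 80.0],
            }
        )

    def test_counts_by_class(self):
        table = build_count_table(self._pauses(), cutoff_ms=293.0)
        f0 = table[(table.speaker_id == "s1") & (table.fragment_id == 0)]
        assert int(f0[f0.pause_class == "short"]["count"].iloc[0]) == 1
        assert int(f0[f0.pause_class == "long"]["count"].iloc[0]) == 1
        assert int(f0[f0.pause_class == "all"]["count"].iloc[0]) == 2

    def test_zero_pause_fragments_from_roster(self):
        roster = pd.DataFrame(
            {
                "speaker_id": ["s1", "s1", "s2", "s2"],
                "group": ["control", "control", "svPPA", "svPPA"],
                "moment": [0, 0, 0, 0],
                "fragment_id": [0, 1, 0, 1],
            }
        )
        table = build_count_table(self._pauses(), 293.0, roster)
        empty = table[(table.speaker_id == "s2") & (table.fragment_id == 1)]
        assert (empty["count"] == 0).all()
        assert empty[empty.pause_class == "all"]["avg_pause_len_ms"].isna().all()

    def test_silence_sums(self):
        table = build_count_table(self._pauses(), 293.0)
        f0 = table[
            (table.speaker_id == "s1")
            & (table.fragment_id == 0)
            & (table.pause_class == "all")
        ]
        assert f0["silence_s"].iloc[0] == pytest.approx(0.7)
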