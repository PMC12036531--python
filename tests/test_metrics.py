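import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from pausekit import (
    SegmentSequence,
    fluency_profile,
    generate_cohort,
    group_anova,
    icc1,
    kruskal_wallis,
    permanova,
)
from pausekit.metrics import fluency_frame
from pausekit.segments import PAUSE, SPEECH


class TestFluencyProfile:
    def test_basic_arithmetic(self):
        seq = SegmentSequence.from_durations([4, 1, 5], [SPEECH, PAUSE, SPEECH])
        p = fluency_profile(seq)
        assert p.locution_time_s == pytest.approx(10.0)
        assert p.phonation_time_s == pytest.approx(9.0)
        assert p.proportion_silence == pytest.approx(0.1)
        assert p.n_pauses == 1
        assert p.avg_pause_len_ms == pytest.approx(1000.0)
        assert p.pause_rate == pytest.approx(1 / 9)

    def test_all_speech_rate_zero_avg_undefined(self):
        p = fluency_profile(SegmentSequence([(0, 5, SPEECH)]))
        assert p.proportion_silence == 0.0
        assert p.pause_rate == 0.0
        assert math.isnan(p.avg_pause_len_ms)
        assert not p.avg_defined

    def test_locution_denominator_option(self):
        seq = SegmentSequence.from_durations([4, 1, 5], [SPEECH, PAUSE, SPEECH])
        p = fluency_profile(seq, rate_denominator="locution")
        assert p.pause_rate == pytest.approx(1 / 10)
        with pytest.raises(ValueError):
            fluency_profile(seq, rate_denominator="nonsense")

    @given(
        st.lists(st.floats(min_value=0.06, max_value=8.0), min_size=1, max_size=10)
    )
    def test_average_length_identity(self, durations):
        """avg pause length x pause count recovers total silence."""
        parts, labels = [], []
        for d in durations:
            parts += [1.0, d]
            labels += [SPEECH, PAUSE]
        seq = SegmentSequence.from_durations(parts, labels)
        p = fluency_profile(seq)
        assert p.avg_pause_len_ms * p.n_pauses / 1000.0 == pytest.approx(
            p.silence_time_s, rel=1e-9
        )

    def test_partition_identity(self):
        seq = SegmentSequence.from_durations([2, 0.5, 3, 0.25], [SPEECH, PAUSE, SPEECH, PAUSE])
        p = fluency_profile(seq)
        assert p.phonation_time_s + p.silence_time_s == pytest.approx(
            p.locution_time_s, abs=1e-6
        )


class TestGroupAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = group_anova(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t**2, rel=1e-9)

    def test_df_three_groups_41_samples(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=41)
        groups = ["a"] * 14 + ["b"] * 12 + ["c"] * 15
        res = group_anova(vals, groups)
        assert res.df == (2, 38)

    def test_constant_data_returns_zero_f(self):
        res = group_anova([1.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_contrasts_table_and_bonferroni(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10), rng.normal(6, 1, 10)])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = group_anova(vals, groups)
        resb = group_anova(vals, groups, bonferroni=True)
        assert len(res.contrasts) == 3
        assert (res.contrasts["ci_low"] <= res.contrasts["ci_high"]).all()
        assert (resb.contrasts["p_adj"] >= res.contrasts["p_adj"] - 1e-15).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


def _oracle_pseudo_f(X, groups):
    """Independent pseudo-F via explicit double loops over distances."""
    d = squareform(pdist(X, metric="braycurtis"))
    n = len(groups)
    labels = sorted(set(groups))
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        ss_w += sum(
            d[i, j] ** 2 for a, i in enumerate(idx) for j in idx[a + 1 :]
        ) / len(idx)
    ss_a = ss_t - ss_w
    k = len(labels)
    return (ss_a / (k - 1)) / (ss_w / (n - k))


class TestPermanova:
    def test_exhaustive_matches_enumeration_oracle(self):
        """Exhaustive p equals a from-scratch enumeration over all 20 splits."""
        rng = np.random.default_rng(3)
        X = rng.random((6, 3))
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(X, groups, exhaustive=True)
        f_obs = _oracle_pseudo_f(X, list(groups))
        count, total = 0, 0
        for combo in itertools.combinations(range(6), 3):
            g = np.array(["b"] * 6)
            for i in combo:
                g[i] = "a"
            total += 1
            if _oracle_pseudo_f(X, list(g)) >= f_obs - 1e-12:
                count += 1
        assert res.statistic == pytest.approx(f_obs, rel=1e-9)
        assert res.p_value == pytest.approx(count / total)

    def test_null_identical_rows(self):
        X = np.ones((8, 3))
        res = permanova(X, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert res.p_value >= 0.5

    def test_power_on_separated_groups(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.random((10, 3)) + 5, rng.random((10, 3)) + 0.1])
        res = permanova(X, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_matches_skbio_pseudo_f(self):
        """Cross-check the pseudo-F against scikit-bio's PERMANOVA."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        X = rng.random((12, 4))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        dm = skbio_stats.DistanceMatrix(squareform(pdist(X, metric="braycurtis")))
        ref = skbio_stats.permanova(dm, grouping=groups, permutations=99)
        res = permanova(X, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_negative_features_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.array([[-1.0, 2.0], [1.0, 2.0]]), ["a", "b"], n_perm=99)


class TestKruskalWallis:
    def test_df_three_groups(self):
        rng = np.random.default_rng(6)
        res = kruskal_wallis(rng.normal(size=29), ["a"] * 14 + ["b"] * 7 + ["c"] * 8)
        assert res.df == 2

    def test_identical_values_h_zero(self):
        res = kruskal_wallis([2.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.statistic == 0.0

    def test_matches_rank_formula_by_hand(self):
        """Small untied instance vs the direct rank-sum formula."""
        vals = [1.0, 3.0, 5.0, 2.0, 4.0, 9.0, 6.0, 7.0, 8.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ranks = stats.rankdata(vals)
        n = len(vals)
        h = 12 / (n * (n + 1)) * sum(
            len(idx := [i for i, g in enumerate(groups) if g == lab])
            * (np.mean(ranks[idx]) ** 2)
            for lab in "abc"
        ) - 3 * (n + 1)
        res = kruskal_wallis(vals, groups)
        assert res.statistic == pytest.approx(h, rel=1e-12)


class TestICC1:
    def test_perfect_speaker_separation(self):
        vals = [1, 1, 1, 5, 5, 5, 9, 9, 9]
        ids = ["s1"] * 3 + ["s2"] * 3 + ["s3"] * 3
        assert icc1(vals, ids) > 0.98

    def test_shuffled_labels_near_zero(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=60)
        ids = rng.permutation(np.repeat([f"s{i}" for i in range(10)], 6))
        assert icc1(vals, ids) < 0.2

    def test_matches_mean_squares_by_hand(self):
        """Balanced two-speaker table vs the one-way variance-component formula."""
        vals = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        ids = ["a"] * 3 + ["b"] * 3
        msb = 3 * ((2 - 5) ** 2 + (8 - 5) ** 2) / 1
        msw = sum((v - 2) ** 2 for v in vals[:3]) + sum((v - 8) ** 2 for v in vals[3:])
        msw /= 4
        var_b = (msb - msw) / 3
        expected = var_b / (var_b + msw)
        assert icc1(vals, ids) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self):
        """Cross-check against pingouin's one-way random-effects ICC1."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n_spk, n_rep = 8, 4
        effects = rng.normal(0, 2, n_spk)
        vals = (effects[:, None] + rng.normal(0, 1, (n_spk, n_rep))).ravel()
        ids = np.repeat([f"s{i}" for i in range(n_spk)], n_rep)
        df = pd.DataFrame(
            {"targets": ids, "raters": list(range(n_rep)) * n_spk, "score": vals}
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
        icc1_ref = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        assert icc1(vals, ids) == pytest.approx(icc1_ref, abs=1e-6)

    def test_single_speaker_rejected(self):
        with pytest.raises(ValueError):
            icc1([1.0, 2.0], ["a", "a"])


class TestGroupDirectionality:
    def test_patient_groups_pause_more_than_controls(self):
        """Group-mean orderings on a default synthetic cohort."""
        cohort = generate_cohort((14, 7, 8), fragments_per_speaker=5, seed=7)
        tagged = [
            ({"group": sp.group}, seq) for sp, _, _, seq in cohort.iter_fragments()
        ]
        frame = fluency_frame(tagged)
        means = frame.groupby("group")[["proportion_silence", "pause_rate"]].mean()
        assert means.loc["control", "proportion_silence"] < means.loc["nfvPPA", "proportion_silence"]
        assert means.loc["control", "proportion_silence"] < means.loc["svPPA", "proportion_silence"]
        assert means.loc["control", "pause_rate"] < means.loc["nfvPPA", "pause_rate"]
        assert means.loc["control", "pause_rate"] < means.loc["svPPA", "pause_rate"]

    def test_permanova_and_anova_agree_on_large_effects(self):
        """Both tests reject together on well-separated univariate input."""
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(1, 0.2, 15), rng.normal(4, 0.2, 15)])
        groups = ["a"] * 15 + ["b"] * 15
        res_a = group_anova(vals, groups)
        res_p = permanova(vals[:, None], groups, n_perm=999, seed=2)
        assert res_a.p_value < 0.01 and res_p.p_value < 0.01
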