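"""Fluency variables and the group-level statistical battery.

Per narration (or fragment) the package reports locution time, phonation
time, silence time, pause count and rate, proportion of silence and the
average pause length (silence divided by pause count).  Group differences
are assessed with one-way ANOVA plus Tukey HSD contrasts, a Bray-Curtis
PERMANOVA as a distribution-free confirmation, Kruskal-Wallis for ordinal
covariates, and ICC1 to quantify how much variance repeated samples from
the same speaker share.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .segments import SegmentSequence


@dataclass(frozen=True)
class FluencyProfile:
    """Fluency variables of one narration or fragment.

    ``avg_pause_len_ms`` is NaN when the narration contains no pauses (the
    quantity is undefined, not zero); ``pause_rate`` is pauses per second
    of the configured denominator time.
    """

    locution_time_s: float
    phonation_time_s: float
    silence_time_s: float
    n_pauses: int
    pause_rate: float
    proportion_silence: float
    avg_pause_len_ms: float

    @property
    def avg_defined(self) -> bool:
        return not math.isnan(self.avg_pause_len_ms)


def fluency_profile(
    segments: SegmentSequence, rate_denominator: str = "phonation"
) -> FluencyProfile:
    """Compute the fluency variables of one segment sequence.

    ``rate_denominator`` selects the time base of the pause rate:
    ``"phonation"`` (pauses per second spoken, the default) or
    ``"locution"`` (pauses per second of total narration time).
    """
    if rate_denominator not in ("phonation", "locution"):
        raise ValueError("rate_denominator must be 'phonation' or 'locution'")
    locution = segments.duration
    if locution <= 0:
        raise ValueError("zero-duration sequence")
    phonation = segments.speech_time
    silence = segments.pause_time
    n = segments.n_pauses
    denom = phonation if rate_denominator == "phonation" else locution
    rate = n / denom if denom > 0 else math.nan
    avg = (silence * 1000.0) / n if n > 0 else math.nan
    return FluencyProfile(
        locution_time_s=locution,
        phonation_time_s=phonation,
        silence_time_s=silence,
        n_pauses=n,
        pause_rate=rate,
        proportion_silence=silence / locution,
        avg_pause_len_ms=avg,
    )


def fluency_frame(
    tagged_sequences, rate_denominator: str = "phonation"
) -> pd.DataFrame:
    """Tidy per-fragment metrics from (metadata_dict, SegmentSequence) pairs."""
    rows = []
    for meta, seq in tagged_sequences:
        prof = fluency_profile(seq, rate_denominator)
        rows.append({**meta, **vars(prof)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Statistic, degrees of freedom, p-value and per-pair contrasts."""

    statistic: float
    df: tuple | float
    p_value: float
    contrasts: pd.DataFrame | None = None
    method: str = ""


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    return values, groups, labels, [values[groups == g] for g in labels]


def group_anova(values, groups, bonferroni: bool = False) -> GroupTestResult:
    """One-way ANOVA with Tukey HSD pairwise contrasts.

    With ``bonferroni=True`` the Tukey pairwise p-values are additionally
    Bonferroni-adjusted across the pairs.
    """
    values, groups, labels, parts = _split_groups(values, groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(p) < 2 for p in parts):
        raise ValueError("every group needs at least 2 samples")
    df = (len(labels) - 1, len(values) - len(labels))
    if np.ptp(values) == 0:  # fully constant data: no effect, by convention
        rows = [
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "difference": 0.0,
                "ci_low": 0.0,
                "ci_high": 0.0,
                "p_adj": 1.0,
            }
            for i, j in itertools.combinations(range(len(labels)), 2)
        ]
        return GroupTestResult(0.0, df, 1.0, pd.DataFrame(rows), "one-way ANOVA (constant data)")
    f, p = stats.f_oneway(*parts)
    tk = stats.tukey_hsd(*parts)
    ci = tk.confidence_interval(0.95)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        p_pair = float(tk.pvalue[i, j])
        if bonferroni:
            p_pair = min(1.0, p_pair * n_pairs)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "difference": float(np.mean(parts[i]) - np.mean(parts[j])),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
                "p_adj": p_pair,
            }
        )
    return GroupTestResult(
        statistic=float(f),
        df=df,
        p_value=float(p),
        contrasts=pd.DataFrame(rows),
        method="one-way ANOVA + Tukey HSD" + (" + Bonferroni" if bonferroni else ""),
    )


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, labels) -> float:
    """PERMANOVA pseudo-F from a squared distance matrix."""
    n = len(groups)
    k = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_total == 0:
        return 0.0
    if ss_within == 0:
        return math.inf
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    features,
    groups,
    n_perm: int = 999,
    seed=None,
    *,
    metric: str = "braycurtis",
    exhaustive: bool = False,
) -> GroupTestResult:
    """Permutational multivariate ANOVA on a Bray-Curtis distance matrix.

    The p-value uses the add-one estimator ``(1 + #{F* >= F}) / (1 + n_perm)``
    under random label permutations; with ``exhaustive=True`` all distinct
    label assignments are enumerated instead and the p-value is the exact
    fraction ``#{F* >= F} / n_assignments`` (the identity assignment counts
    itself).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if metric == "braycurtis" and (X < 0).any():
        raise ValueError(
            "Bray-Curtis requires non-negative features; shift or rescale them first"
        )
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99 (or use exhaustive=True)")
    d2 = squareform(pdist(X, metric=metric)) ** 2
    f_obs = _pseudo_f(d2, groups, labels)
    if exhaustive:
        seen = set()
        count = 0
        total = 0
        for perm in itertools.permutations(range(len(groups))):
            key = tuple(groups[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if _pseudo_f(d2, np.asarray(key), labels) >= f_obs - 1e-12:
                count += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        g = groups.copy()
        for _ in range(n_perm):
            rng.shuffle(g)
            if _pseudo_f(d2, g, labels) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return GroupTestResult(
        statistic=float(f_obs),
        df=(len(labels) - 1, len(groups) - len(labels)),
        p_value=float(p),
        method=f"PERMANOVA ({metric}, {'exhaustive' if exhaustive else n_used} permutations)",
    )


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Kruskal-Wallis H with tie correction; H=0 for fully tied data."""
    values, groups, labels, parts = _split_groups(values, groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    df = len(labels) - 1
    if np.all(values == values[0]):
        return GroupTestResult(0.0, df, 1.0, method="Kruskal-Wallis")
    h, p = stats.kruskal(*parts)
    return GroupTestResult(float(h), df, float(p), method="Kruskal-Wallis")


def icc1(values, speaker_ids) -> float:
    """One-way random-effects intraclass correlation (ICC1).

    Between-speaker variance is estimated from the one-way ANOVA mean
    squares with the unbalanced-design group-size correction
    ``n0 = (N - sum(n_i^2)/N) / (k - 1)``; negative estimates are truncated
    and the ratio clamped to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    ids = np.asarray(speaker_ids)
    labels = pd.unique(ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 speakers")
    N = len(values)
    k = len(labels)
    grand = values.mean()
    parts = [values[ids == g] for g in labels]
    ns = np.array([len(p) for p in parts], dtype=float)
    ss_between = float(sum(n * (p.mean() - grand) ** 2 for n, p in zip(ns, parts)))
    ss_within = float(sum(((p - p.mean()) ** 2).sum() for p in parts))
    ms_between = ss_between / (k - 1)
    df_within = N - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (N - (ns**2).sum() / N) / (k - 1)
    var_between = max(0.0, (ms_between - ms_within) / n0)
    total = var_between + ms_within
    if total == 0:
        return 0.0
    return float(min(1.0, max(0.0, var_between / total)))
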