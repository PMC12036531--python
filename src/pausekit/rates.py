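"""Bayesian Gamma-Poisson modelling of per-fragment pause counts.

Pause counts per 20-second fragment are overdispersed relative to a Poisson
law; the Gamma-Poisson (negative binomial) distribution with mean ``mu`` and
dispersion ``beta`` (variance ``mu + mu**2 / beta``) describes them well.
:class:`PauseRateModel` places weakly-informative priors on group-specific
``log mu`` and a shared ``beta`` and samples the posterior with an adaptive
random-walk Metropolis sampler; group contrasts are summarised through 89%
highest-density intervals of the difference of matched posterior ``mu``
draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import gammaln

PAUSE_CLASSES = ("short", "long", "all")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def nb_loglik(counts, mu: float, beta: float) -> float:
    """Gamma-Poisson log-likelihood of integer counts.

    Parameterisation: mean ``mu``, dispersion ``beta`` with variance
    ``mu + mu**2 / beta``; the pmf is
    ``C(k + beta - 1, k) (beta/(beta+mu))**beta (mu/(beta+mu))**k``.
    """
    k = np.asarray(counts)
    if k.size == 0:
        return 0.0
    if not np.issubdtype(k.dtype, np.integer):
        kf = np.asarray(counts, dtype=float)
        if not np.all(kf == np.floor(kf)):
            raise ValueError("counts must be integers")
        k = kf.astype(int)
    if (k < 0).any():
        raise ValueError("counts must be non-negative")
    if not (mu > 0 and beta > 0):
        raise ValueError("mu and beta must be > 0")
    k = k.astype(float)
    return float(
        np.sum(
            gammaln(k + beta)
            - gammaln(beta)
            - gammaln(k + 1)
            + beta * (math.log(beta) - math.log(beta + mu))
            + k * (math.log(mu) - math.log(beta + mu))
        )
    )


def sample_nb(rng: np.random.Generator, mu: float, beta: float, size) -> np.ndarray:
    lam = rng.gamma(shape=beta, scale=mu / beta, size=size)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------

_FRAG_KEYS = ["speaker_id", "group", "moment", "fragment_id"]


def build_count_table(
    pauses: pd.DataFrame,
    cutoff_ms: float,
    fragments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-fragment short/long/all pause counts plus silence summaries.

    ``pauses`` holds one row per pause (columns speaker_id, group, moment,
    fragment_id, duration_ms).  ``fragments`` is the full fragment roster so
    fragments without any pause contribute zero counts; without it the
    roster is inferred from the pause table (zero-pause fragments are then
    invisible).  Returns one row per fragment and pause class with columns
    count, silence_s and avg_pause_len_ms.
    """
    if fragments is None:
        roster = pauses[_FRAG_KEYS].drop_duplicates()
    else:
        roster = fragments[_FRAG_KEYS].drop_duplicates()
    p = pauses.copy()
    p["pause_class"] = np.where(p["duration_ms"] < cutoff_ms, "short", "long")
    rows = []
    grouped = {k: v for k, v in p.groupby(_FRAG_KEYS)}
    for key in roster.itertuples(index=False, name=None):
        sub = grouped.get(key)
        for cls in PAUSE_CLASSES:
            if sub is None:
                n, sil = 0, 0.0
            else:
                part = sub if cls == "all" else sub[sub["pause_class"] == cls]
                n = len(part)
                sil = part["duration_ms"].sum() / 1000.0
            rows.append(
                key
                + (cls, n, sil, (sil * 1000.0 / n) if n else math.nan)
            )
    return pd.DataFrame(
        rows,
        columns=_FRAG_KEYS + ["pause_class", "count", "silence_s", "avg_pause_len_ms"],
    )


# ---------------------------------------------------------------------------
# HDI and contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HDIInterval:
    lower: float
    upper: float
    mass: float = 0.89


def hdi(samples, mass: float = 0.89) -> HDIInterval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples."""
    x = np.sort(np.ravel(np.asarray(samples, dtype=float)))
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return HDIInterval(lower=float(x[i]), upper=float(x[i + m - 1]), mass=mass)


@dataclass
class DifferenceSummary:
    """Posterior difference of two group means (mu_A - mu_B)."""

    samples: np.ndarray
    hdi: HDIInterval
    excludes_zero: bool

    @classmethod
    def from_samples(cls, samples: np.ndarray, mass: float = 0.89) -> "DifferenceSummary":
        if np.allclose(samples, samples.flat[0]):
            c = float(samples.flat[0])
            iv = HDIInterval(c, c, mass)
        else:
            iv = hdi(samples, mass)
        return cls(samples=np.ravel(samples), hdi=iv, excludes_zero=not (iv.lower <= 0.0 <= iv.upper))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatePriors:
    """Weakly-informative defaults: log mu ~ N(log 5, 1.5), beta ~ Exp(0.1),
    covariate coefficients ~ N(0, 1)."""

    log_mu_loc: float = math.log(5.0)
    log_mu_scale: float = 1.5
    beta_rate: float = 0.1
    coef_scale: float = 1.0


class _AdaptiveRW:
    """Componentwise random-walk Metropolis with scale adaptation in warmup."""

    def __init__(self, logpost, theta0, rng, target=(0.3, 0.45)):
        self.logpost = logpost
        self.theta = np.asarray(theta0, dtype=float)
        self.rng = rng
        self.scales = np.full(len(self.theta), 0.3)
        self.target = target
        self.lp = logpost(self.theta)
        self.accepts = np.zeros(len(self.theta))
        self.window = 0

    def step(self, adapt: bool) -> np.ndarray:
        for j in range(len(self.theta)):
            prop = self.theta.copy()
            prop[j] += self.rng.normal(0.0, self.scales[j])
            lp_new = self.logpost(prop)
            if math.log(self.rng.random()) < lp_new - self.lp:
                self.theta = prop
                self.lp = lp_new
                self.accepts[j] += 1
        self.window += 1
        if adapt and self.window >= 50:
            rate = self.accepts / self.window
            lo, hi = self.target
            self.scales[rate < lo] *= 0.7
            self.scales[rate > hi] *= 1.4
            self.accepts[:] = 0
            self.window = 0
        return self.theta.copy()


@dataclass
class GroupRatePosterior:
    """Posterior for one pause class: mu per group plus shared beta."""

    pause_class: str
    groups: tuple[str, ...]
    mu: dict  # group -> (n_chains, n_kept) array
    beta: np.ndarray  # (n_chains, n_kept)
    rhat: dict
    ess: dict
    accept_rate: float
    coefs: dict | None = None  # covariate coefficient samples, if fitted

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_kept(self) -> int:
        return self.beta.shape[1]


class PauseRateModel:
    """Gamma-Poisson model of per-fragment pause counts for one pause class.

    The linear predictor is ``log mu_i = a_{group(i)}`` with optional
    centred covariates for the fragment's amount of silence, its average
    pause length, and their interaction:
    ``log mu_i = a_g + b1 z_sil + b2 z_len + b3 z_sil z_len``.
    The dispersion ``beta`` is shared across groups within the class.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        pause_class: str = "all",
        priors: RatePriors | None = None,
        include_covariates: bool = False,
    ) -> None:
        sub = table[table["pause_class"] == pause_class]
        groups = tuple(pd.unique(sub["group"]))
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        for g in groups:
            if (sub["group"] == g).sum() < 10:
                raise ValueError(f"group {g!r} has fewer than 10 fragments")
        self.pause_class = pause_class
        self.groups = groups
        self.priors = priors or RatePriors()
        self.include_covariates = include_covariates
        self._counts = sub["count"].to_numpy(dtype=float)
        self._gidx = np.array([groups.index(g) for g in sub["group"]])
        if include_covariates:
            sil = sub["silence_s"].to_numpy(dtype=float)
            ln = sub["avg_pause_len_ms"].fillna(0.0).to_numpy(dtype=float)
            z1 = (sil - sil.mean()) / (sil.std() or 1.0)
            z2 = (ln - ln.mean()) / (ln.std() or 1.0)
            self._X = np.column_stack([z1, z2, z1 * z2])
        else:
            self._X = None

    # parameter vector: [log mu per group, log beta, (3 covariate coefs)]
    def _logpost(self, theta: np.ndarray) -> float:
        pr = self.priors
        k = len(self.groups)
        log_mu_g = theta[:k]
        log_beta = theta[k]
        if abs(log_beta) > 20 or np.abs(log_mu_g).max() > 20:
            return -math.inf
        beta = math.exp(log_beta)
        eta = log_mu_g[self._gidx]
        if self._X is not None:
            eta = eta + self._X @ theta[k + 1 :]
        mu = np.exp(eta)
        kk = self._counts
        ll = np.sum(
            gammaln(kk + beta)
            - gammaln(beta)
            - gammaln(kk + 1)
            + beta * (log_beta - np.log(beta + mu))
            + kk * (eta - np.log(beta + mu))
        )
        lp = ll
        lp += np.sum(-0.5 * ((log_mu_g - pr.log_mu_loc) / pr.log_mu_scale) ** 2)
        lp += -pr.beta_rate * beta + log_beta  # Exp prior + log-transform Jacobian
        if self._X is not None:
            lp += np.sum(-0.5 * (theta[k + 1 :] / pr.coef_scale) ** 2)
        return float(lp)

    def fit(
        self,
        n_chains: int = 2,
        n_iter: int = 4000,
        warmup: int | None = None,
        seed=None,
        rhat_warn: float = 1.01,
    ) -> GroupRatePosterior:
        """Sample the posterior; returns kept draws with chain diagnostics."""
        warm = n_iter // 2 if warmup is None else warmup
        k = len(self.groups)
        n_cov = 3 if self._X is not None else 0
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        chain_rngs = [np.random.default_rng(s) for s in ss.spawn(n_chains)]
        kept = np.empty((n_chains, n_iter - warm, k + 1 + n_cov))
        acc = 0.0
        for c, rng in enumerate(chain_rngs):
            obs_mean = max(self._counts.mean(), 0.1)
            theta0 = np.concatenate(
                [
                    np.log(obs_mean) + rng.normal(0, 0.3, k),
                    [math.log(5.0) + rng.normal(0, 0.5)],
                    rng.normal(0, 0.1, n_cov),
                ]
            )
            sampler = _AdaptiveRW(self._logpost, theta0, rng)
            prev = sampler.theta.copy()
            n_moves = 0
            for it in range(n_iter):
                th = sampler.step(adapt=it < warm)
                if it >= warm:
                    kept[c, it - warm] = th
                    n_moves += int(not np.array_equal(th, prev))
                prev = th
            acc += n_moves / (n_iter - warm)
        acc /= n_chains

        mu = {g: np.exp(kept[:, :, i]) for i, g in enumerate(self.groups)}
        beta = np.exp(kept[:, :, k])
        names = [f"mu[{g}]" for g in self.groups] + ["beta"]
        arrays = [mu[g] for g in self.groups] + [beta]
        coefs = None
        if n_cov:
            cnames = ["b_silence", "b_length", "b_interaction"]
            coefs = {nm: kept[:, :, k + 1 + i] for i, nm in enumerate(cnames)}
            names += cnames
            arrays += [coefs[nm] for nm in cnames]
        idata = az.from_dict({nm: arr for nm, arr in zip(names, arrays)})
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
        rhat = {nm: float(rhat_ds[nm].values) for nm in names}
        ess = {nm: float(ess_ds[nm].values) for nm in names}
        bad = {nm: v for nm, v in rhat.items() if not np.isfinite(v) or v > rhat_warn}
        if bad:
            warnings.warn(
                f"MCMC convergence suspect for {self.pause_class!r}: rhat {bad}; "
                "increase n_iter or check the data",
                RuntimeWarning,
            )
        return GroupRatePosterior(
            pause_class=self.pause_class,
            groups=self.groups,
            mu=mu,
            beta=beta,
            rhat=rhat,
            ess=ess,
            accept_rate=float(acc),
            coefs=coefs,
        )


@dataclass
class RatePosterior:
    """Posteriors for several pause classes, keyed by class name."""

    by_class: dict

    def __getitem__(self, pause_class: str) -> GroupRatePosterior:
        return self.by_class[pause_class]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.by_class)

    def summary(self, mass: float = 0.89) -> pd.DataFrame:
        rows = []
        for cls, post in self.by_class.items():
            items = [(f"mu[{g}]", post.mu[g]) for g in post.groups] + [("beta", post.beta)]
            for name, arr in items:
                iv = hdi(arr, mass)
                rows.append(
                    {
                        "pause_class": cls,
                        "parameter": name,
                        "mean": float(arr.mean()),
                        f"hdi_{mass:g}_lower": iv.lower,
                        f"hdi_{mass:g}_upper": iv.upper,
                        "rhat": post.rhat[name],
                        "ess": post.ess[name],
                    }
                )
        return pd.DataFrame(rows)


def fit_rate_model(
    table: pd.DataFrame,
    priors: RatePriors | None = None,
    n_chains: int = 2,
    n_iter: int = 4000,
    seed=None,
    classes=("short", "long"),
    include_covariates: bool = False,
) -> RatePosterior:
    """Fit the Gamma-Poisson rate model for each requested pause class."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(classes))
    by_class = {}
    for cls, s in zip(classes, child):
        model = PauseRateModel(
            table, pause_class=cls, priors=priors, include_covariates=include_covariates
        )
        by_class[cls] = model.fit(n_chains=n_chains, n_iter=n_iter, seed=s)
    return RatePosterior(by_class=by_class)


def group_mu_difference(
    posterior: RatePosterior | GroupRatePosterior,
    group_a: str,
    group_b: str,
    pause_class: str | None = None,
    mass: float = 0.89,
) -> DifferenceSummary:
    """Posterior of mu_A - mu_B over matched draws, with its HDI."""
    if isinstance(posterior, RatePosterior):
        if pause_class is None:
            raise KeyError("pause_class required with a multi-class posterior")
        posterior = posterior[pause_class]
    for g in (group_a, group_b):
        if g not in posterior.mu:
            raise KeyError(f"unknown group {g!r}; have {posterior.groups}")
    diff = posterior.mu[group_a] - posterior.mu[group_b]
    return DifferenceSummary.from_samples(diff, mass)


@dataclass
class PPCResult:
    """Observed vs posterior-predicted count distribution for one group."""

    group: str
    bins: np.ndarray
    observed_density: np.ndarray
    predicted_density: np.ndarray
    tv_distance: float


def posterior_predictive_check(
    posterior: GroupRatePosterior,
    table: pd.DataFrame,
    seed=None,
    n_draws: int = 500,
) -> dict:
    """Simulate replicate counts per group and score the density overlap.

    Returns ``{group: PPCResult}`` where ``tv_distance`` is the total
    variation distance between the observed count pmf and the posterior
    predictive pmf (0 = identical); groups without fragments are skipped
    with a warning.
    """
    rng = np.random.default_rng(seed)
    sub = table[table["pause_class"] == posterior.pause_class]
    out = {}
    mu_flat = {g: posterior.mu[g].ravel() for g in posterior.groups}
    beta_flat = posterior.beta.ravel()
    for g in posterior.groups:
        counts = sub[sub["group"] == g]["count"].to_numpy()
        if counts.size == 0:
            warnings.warn(f"group {g!r} has no fragments; excluded from PPC")
            continue
        idx = rng.integers(0, len(beta_flat), size=n_draws)
        sims = np.concatenate(
            [sample_nb(rng, mu_flat[g][i], beta_flat[i], counts.size) for i in idx]
        )
        top = int(max(counts.max(), sims.max())) + 1
        bins = np.arange(top + 1)
        obs_p = np.bincount(counts, minlength=top) / counts.size
        sim_p = np.bincount(sims, minlength=top) / sims.size
        tv = 0.5 * float(np.abs(obs_p - sim_p).sum())
        out[g] = PPCResult(
            group=g,
            bins=bins[:-1],
            observed_density=obs_p,
            predicted_density=sim_p,
            tv_distance=tv,
        )
    return out
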