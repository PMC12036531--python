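"""Two-component Gaussian mixture modelling of pause durations.

Pause durations in connected speech are bimodal: a short-pause class
(articulatory/breathing interruptions) and a long-pause class (cognitive or
discourse pauses).  :class:`PauseMixtureModel` fits a k-component Gaussian
mixture to observed durations by EM and :meth:`PauseMixtureResults.cutoff_ms`
derives the data-driven boundary between the classes as the point where the
weighted densities of the two components intersect.

Because the pause detector discards everything below 50 ms, every observed
duration is left-truncated at that floor.  The EM therefore models each
component as a left-truncated Gaussian by default (the M-step matches the
responsibility-weighted sample moments to truncated-normal moments, which is
the exact maximum-likelihood update since the truncated normal is an
exponential family).  Fitting can run on linear milliseconds (default) or on
log10(ms); plain untruncated components are available with
``truncate_at_ms=None``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .profiles import LINEAR_MS, LOG10_MS, MIN_PAUSE_MS, GaussianComponent


class NoCrossingError(ValueError):
    """The weighted component densities do not intersect between the means."""


class DegenerateFitError(RuntimeError):
    """Every EM start collapsed onto a degenerate (zero-variance) component."""


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _trunc_lambda(alpha):
    """Inverse Mills ratio phi(a) / (1 - Phi(a)), numerically stable."""
    a = np.asarray(alpha, dtype=float)
    return np.exp(-0.5 * a * a - _LOG_SQRT_2PI - special.log_ndtr(-a))


def _solve_truncated_moments(xbar: float, v: float, a: float):
    """Solve E[X]=xbar, Var[X]=v for a normal left-truncated at ``a``.

    With alpha = (a - mean)/sd and lambda the inverse Mills ratio, the moment
    equations reduce to the 1-D problem
    ``(1 + alpha*lambda - lambda^2) / (lambda - alpha)^2 = v / (xbar - a)^2``
    whose left side increases monotonically from 0 (alpha -> -inf, no
    truncation) to 1 (alpha -> +inf, exponential-tail limit).  The ratio is
    clipped into the solvable range, which caps how deep below the floor a
    component mean may sit.
    """
    delta = xbar - a
    if not delta > 0 or not v > 0:
        return None

    def ratio(alpha: float) -> float:
        lam = float(_trunc_lambda(np.array([alpha]))[0])
        return (1.0 + alpha * lam - lam * lam) / (lam - alpha) ** 2

    lo, hi = -30.0, 30.0
    target = min(max(v / delta**2, ratio(lo) * 1.001), ratio(hi) * 0.999)
    alpha = optimize.brentq(lambda t: ratio(t) - target, lo, hi, xtol=1e-10)
    lam = float(_trunc_lambda(np.array([alpha]))[0])
    s = delta / (lam - alpha)
    m = a - alpha * s

    # constrain the component mean to stay positive: on the boundary the
    # M-step profiles the likelihood over the scale only, so the update
    # remains a (constrained) maximiser and EM stays monotone
    m_min = max(1e-3, 1e-6 * a)
    if m < m_min:
        m = m_min
        sw2 = v + delta**2 + 2 * delta * (a - m) + (a - m) ** 2  # E_w[(x-m)^2]

        def neg_profile(ls: float) -> float:
            sj = math.exp(ls)
            return (
                ls
                + sw2 / (2.0 * sj * sj)
                + float(special.log_ndtr((m - a) / sj))
            )

        res = optimize.minimize_scalar(
            neg_profile, bounds=(math.log(1e-6 * max(a, 1.0)), math.log(1e6)), method="bounded"
        )
        s = math.exp(res.x)
    return float(m), float(s)


def _em(
    x: np.ndarray,
    k: int,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    floor: float | None,
    tol: float,
    max_iter: int,
):
    """Run EM from one start; returns (means, sds, weights, trace, converged)."""
    n = len(x)
    scale = x.std() or 1.0
    means, sds, weights = means.copy(), sds.copy(), weights.copy()
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E-step: responsibilities under (truncated) component densities
        logp = np.empty((k, n))
        for j in range(k):
            z = (x - means[j]) / sds[j]
            logp[j] = (
                math.log(weights[j]) - 0.5 * z * z - _LOG_SQRT_2PI - math.log(sds[j])
            )
            if floor is not None:
                logp[j] -= special.log_ndtr((means[j] - floor) / sds[j])
        mx = logp.max(axis=0)
        tot = mx + np.log(np.exp(logp - mx).sum(axis=0))
        ll = float(tot.sum())
        trace.append(ll)
        r = np.exp(logp - tot)
        # M-step
        rk = r.sum(axis=1)
        if (rk < 1e-10).any():
            return None
        weights = rk / n
        for j in range(k):
            rw = r[j] / rk[j]
            xbar = float(rw @ x)
            v = float(rw @ (x - xbar) ** 2)
            if v < (1e-6 * scale) ** 2:
                return None  # degenerate component
            if floor is None:
                means[j], sds[j] = xbar, math.sqrt(v)
            else:
                sol = _solve_truncated_moments(xbar, v, floor)
                if sol is None or sol[1] < 1e-6 * scale:
                    return None
                means[j], sds[j] = sol
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return means, sds, weights, trace, converged


@dataclass
class PauseMixtureResults:
    """Fitted pause-duration mixture.

    ``components`` are sorted by ascending mean and expressed in the fit
    domain; ``loglik_trace`` is the per-iteration log-likelihood of the best
    start and is non-decreasing; ``bic`` supports comparing component counts.
    """

    k: int
    components: tuple[GaussianComponent, ...]
    domain: str
    truncate_at_ms: float | None
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    bic: float

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def lambda_long(self) -> float:
        """Mixing weight of the longest-pause component."""
        return self.components[-1].weight

    def cutoff_ms(self) -> float:
        """Short/long boundary: intersection of the two weighted densities."""
        if self.k != 2:
            raise ValueError("cutoff is defined for two-component fits")
        return pause_cutoff(self.components[0], self.components[1])

    def classify(self, durations_ms) -> tuple[np.ndarray, dict]:
        return classify_pauses(durations_ms, self.cutoff_ms())

    def summary(self) -> str:
        lines = [
            f"PauseMixtureResults: k={self.k}, domain={self.domain}, "
            f"n={self.n_obs}, floor={self.truncate_at_ms} ms",
            f"  loglik={self.loglik:.3f}  BIC={self.bic:.3f}  "
            f"converged={self.converged} ({self.n_iter} iterations)",
        ]
        for tag, c in zip(("short", "long", "extra"), self.components):
            lines.append(
                f"  {tag:>5}: mean={c.mean:10.3f}  sd={c.sd:9.3f}  lambda={c.weight:.3f}"
            )
        if self.k == 2:
            try:
                lines.append(f"  cutoff = {self.cutoff_ms():.1f} ms")
            except NoCrossingError:
                lines.append("  cutoff undefined (densities do not cross)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "domain": self.domain,
            "truncate_at_ms": self.truncate_at_ms,
            "components": [vars(c).copy() for c in self.components],
            "loglik": self.loglik,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
        }


class PauseMixtureModel:
    """Gaussian mixture model for pause durations.

    Parameters
    ----------
    durations_ms
        Observed pause durations in milliseconds, all >= 50 ms.
    k
        Number of mixture components (2 for the short/long analysis).
    domain
        ``"linear_ms"`` fits Gaussians to the raw millisecond durations
        (default); ``"log10_ms"`` fits them to log10 durations.
    truncate_at_ms
        Left-truncation floor in ms (default 50, matching the pause
        detector); ``None`` fits plain untruncated Gaussians.
    """

    def __init__(
        self,
        durations_ms,
        k: int = 2,
        *,
        domain: str = LINEAR_MS,
        truncate_at_ms: float | None = MIN_PAUSE_MS,
    ) -> None:
        d = np.asarray(durations_ms, dtype=float)
        if d.ndim != 1 or len(d) < 10:
            raise ValueError("need a 1-D array of at least 10 durations")
        if len(d) < 5 * k:
            raise ValueError(f"need at least {5 * k} durations for k={k}")
        if (d < MIN_PAUSE_MS - 1e-9).any():
            raise ValueError(f"durations below the {MIN_PAUSE_MS} ms floor")
        if domain not in (LINEAR_MS, LOG10_MS):
            raise ValueError(f"unknown domain {domain!r}")
        self.durations_ms = d
        self.k = int(k)
        self.domain = domain
        self.truncate_at_ms = truncate_at_ms
        self._x = d if domain == LINEAR_MS else np.log10(d)
        self._floor = (
            None
            if truncate_at_ms is None
            else (truncate_at_ms if domain == LINEAR_MS else math.log10(truncate_at_ms))
        )

    def fit(
        self,
        n_starts: int = 8,
        tol: float = 1e-8,
        max_iter: int = 500,
        seed=None,
    ) -> PauseMixtureResults:
        """Fit by EM with quantile-based and random restarts; keep the best."""
        x, k = self._x, self.k
        rng = np.random.default_rng(seed)
        best = None
        n_failed = 0
        for start in range(max(1, n_starts)):
            if start == 0:  # k-quantile split
                qs = np.quantile(x, np.linspace(0, 1, k + 1))
                means, sds = [], []
                for i in range(k):
                    part = x[(x >= qs[i]) & (x <= qs[i + 1])]
                    if len(part) < 2:
                        part = x
                    means.append(part.mean())
                    sds.append(max(part.std(), 1e-3 * (x.std() or 1.0)))
                means, sds = np.array(means), np.array(sds)
                weights = np.full(k, 1.0 / k)
            else:  # random start: perturbed quantiles of the data
                means = np.sort(rng.choice(x, size=k, replace=False))
                sds = np.full(k, x.std() / k + 1e-9)
                weights = rng.dirichlet(np.full(k, 5.0))
            res = _em(x, k, means, sds, weights, self._floor, tol, max_iter)
            if res is None or (self.domain == LINEAR_MS and (res[0] <= 0).any()):
                # collapsed, or a truncated component slid wholly below 0 ms
                n_failed += 1
                continue
            if best is None or res[3][-1] > best[3][-1]:
                best = res
        if best is None:
            raise DegenerateFitError(
                f"all {n_starts} EM starts degenerated (n={len(x)}, k={k})"
            )
        means, sds, weights, trace, converged = best
        order = np.argsort(means)
        comps = tuple(
            GaussianComponent(float(means[j]), float(sds[j]), float(weights[j]), self.domain)
            for j in order
        )
        n_params = 3 * k - 1
        bic = -2.0 * trace[-1] + n_params * math.log(len(x))
        if not converged:
            warnings.warn("EM reached max_iter without meeting tol", RuntimeWarning)
        return PauseMixtureResults(
            k=k,
            components=comps,
            domain=self.domain,
            truncate_at_ms=self.truncate_at_ms,
            loglik_trace=np.asarray(trace),
            converged=converged,
            n_iter=len(trace),
            n_obs=len(x),
            bic=bic,
        )


def fit_pause_mixture(
    durations_ms,
    k: int = 2,
    n_starts: int = 8,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed=None,
    **model_kwargs,
) -> PauseMixtureResults:
    """Convenience wrapper: build a :class:`PauseMixtureModel` and fit it."""
    return PauseMixtureModel(durations_ms, k, **model_kwargs).fit(
        n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed
    )


# ---------------------------------------------------------------------------
# cutoff and classification
# ---------------------------------------------------------------------------

def pause_cutoff(
    short: GaussianComponent, long: GaussianComponent, xtol_ms: float = 0.01
) -> float:
    """Duration (ms) at which the weighted densities of the components cross.

    Finds the unique root of ``w_s * N(x; short) = w_l * N(x; long)``
    strictly between the two component means by bracketed root finding.
    Components may be in either domain (both the same); log-domain roots are
    returned back-transformed to milliseconds.
    """
    if short.domain != long.domain:
        raise ValueError("components must share a domain")
    a, b = sorted((short, long), key=lambda c: c.mean)
    if a.mean == b.mean and a.sd == b.sd:
        raise NoCrossingError("identical components have no defined cutoff")
    if not a.mean < b.mean:
        raise ValueError("component means must differ")

    def f(x):
        return a.weight * stats.norm.pdf(x, a.mean, a.sd) - b.weight * stats.norm.pdf(
            x, b.mean, b.sd
        )

    fa, fb = f(a.mean), f(b.mean)
    if not (fa > 0 > fb):
        raise NoCrossingError(
            "weighted densities do not cross between the component means "
            f"(f(mean_short)={fa:.3g}, f(mean_long)={fb:.3g})"
        )
    xtol = xtol_ms if a.domain == LINEAR_MS else 1e-9
    root = optimize.brentq(f, a.mean, b.mean, xtol=xtol)
    return float(root if a.domain == LINEAR_MS else 10.0**root)


def classify_pauses(durations_ms, cutoff_ms: float) -> tuple[np.ndarray, dict]:
    """Label each pause short/long; values at the cutoff are long.

    Returns ``(labels, counts)`` where labels is an array of ``"short"`` /
    ``"long"`` and counts maps each class to its count.
    """
    if not cutoff_ms > MIN_PAUSE_MS:
        raise ValueError(f"cutoff must exceed the {MIN_PAUSE_MS} ms pause floor")
    d = np.asarray(durations_ms, dtype=float)
    labels = np.where(d < cutoff_ms, "short", "long")
    counts = {
        "short": int((labels == "short").sum()),
        "long": int((labels == "long").sum()),
    }
    return labels, counts


# ---------------------------------------------------------------------------
# component-sampling comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentComparison:
    """Welch t and Cohen's d between samples from two component Gaussians."""

    t_statistic: float
    welch_df: float
    p_value: float
    cohens_d: float
    n_per_side: int


def compare_components(
    a: GaussianComponent, b: GaussianComponent, n: int = 1000, seed=None
) -> ComponentComparison:
    """Monte-Carlo comparison of two components (n samples per side).

    Draws ``n`` values from each component's Gaussian (linear-ms domain),
    then computes Welch's unequal-variance t with Welch-Satterthwaite
    degrees of freedom and Cohen's d with pooled SD
    ``sqrt((s_a^2 + s_b^2) / 2)``.
    """
    if a.domain != LINEAR_MS or b.domain != LINEAR_MS:
        raise ValueError("compare_components expects linear-ms components")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    xa = rng.normal(a.mean, a.sd, n)
    xb = rng.normal(b.mean, b.sd, n)
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    se2 = va / n + vb / n
    t = (xa.mean() - xb.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    d = (xa.mean() - xb.mean()) / math.sqrt((va + vb) / 2.0)
    return ComponentComparison(
        t_statistic=float(t),
        welch_df=float(df),
        p_value=float(p),
        cohens_d=float(d),
        n_per_side=n,
    )
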