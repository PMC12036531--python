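"""Group-level pause distribution profiles.

Each speaker group (healthy controls, nonfluent-variant PPA, semantic-variant
PPA) is described by a two-component Gaussian mixture over pause durations
plus a Gamma-Poisson law for the number of pauses per 20-second fragment.
The default parameter values are the published group characteristics for
Dutch picture-description speech; they drive the synthetic-data generator
and the component-level effect-size comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

LINEAR_MS = "linear_ms"
LOG10_MS = "log10_ms"
_DOMAINS = (LINEAR_MS, LOG10_MS)

GROUPS = ("control", "nfvPPA", "svPPA")

#: Minimum pause duration considered by the whole pipeline (ms).
MIN_PAUSE_MS = 50.0


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian component of a pause-duration mixture.

    ``domain`` states whether ``mean`` and ``sd`` are expressed in linear
    milliseconds or in log10(ms); ``weight`` is the mixing proportion
    (lambda) of the component.
    """

    mean: float
    sd: float
    weight: float
    domain: str = LINEAR_MS

    def __post_init__(self) -> None:
        if self.domain not in _DOMAINS:
            raise ValueError(f"domain must be one of {_DOMAINS}, got {self.domain!r}")
        if not self.sd > 0:
            raise ValueError("component sd must be > 0")
        if not 0 < self.weight <= 1:  # weight 1 covers the single-component fit
            raise ValueError("component weight must be in (0, 1]")
        if self.domain == LINEAR_MS and not self.mean > 0:
            raise ValueError("linear-domain component mean must be > 0 ms")


@dataclass(frozen=True)
class GroupProfile:
    """Generating parameters for one speaker group.

    ``rate_mu`` is the expected number of pauses per 20-s fragment and
    ``rate_beta`` the Gamma-Poisson dispersion, with count variance
    ``mu + mu**2 / beta``.  ``target_proportion_silence`` records the
    published group-mean proportion of silence; it is descriptive (the
    realised proportion emerges from ``rate_mu`` and the duration mixture).
    """

    group: str
    short: GaussianComponent
    long: GaussianComponent
    rate_mu: float
    rate_beta: float
    target_proportion_silence: float

    def __post_init__(self) -> None:
        if self.short.domain != self.long.domain:
            raise ValueError("short and long components must share a domain")
        if abs(self.short.weight + self.long.weight - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if not self.short.mean < self.long.mean:
            raise ValueError("short component mean must lie below long component mean")
        # rate_mu == 0 is permitted as the degenerate no-pause limit
        if self.rate_mu < 0:
            raise ValueError("rate_mu must be >= 0")
        if not self.rate_beta > 0:
            raise ValueError("rate_beta must be > 0")
        if not 0 <= self.target_proportion_silence <= 1:
            raise ValueError("target_proportion_silence must be in [0, 1]")

    @property
    def domain(self) -> str:
        return self.short.domain

    def with_rate(self, rate_mu: float | None = None, rate_beta: float | None = None) -> "GroupProfile":
        return replace(
            self,
            rate_mu=self.rate_mu if rate_mu is None else rate_mu,
            rate_beta=self.rate_beta if rate_beta is None else rate_beta,
        )


# Published group characteristics (linear-ms reading of the component table;
# pause rate in pauses per second, proportion of silence as a fraction).
_TABLE = {
    "control": dict(
        short=(165.22, 86.78, 0.29),
        long=(759.97, 505.31, 0.71),
        pause_rate_per_s=0.23,
        proportion_silence=0.21,
    ),
    "nfvPPA": dict(
        short=(285.20, 253.26, 0.37),
        long=(1691.74, 151.78, 0.63),
        pause_rate_per_s=0.40,
        proportion_silence=0.61,
    ),
    "svPPA": dict(
        short=(71.62, 17.96, 0.07),
        long=(767.49, 794.64, 0.93),
        pause_rate_per_s=0.41,
        proportion_silence=0.50,
    ),
}

#: Default Gamma-Poisson dispersion (the source analysis names the dispersion
#: parameter but does not print its value; 10 gives mild overdispersion).
DEFAULT_RATE_BETA = 10.0

#: Nominal analysis fragment length in seconds.
FRAGMENT_S = 20.0


def default_group_profiles(
    rate_beta: float = DEFAULT_RATE_BETA, fragment_s: float = FRAGMENT_S
) -> dict[str, GroupProfile]:
    """Return the default per-group generating profiles.

    Component means/SDs/weights are the published linear-millisecond values;
    ``rate_mu`` is the published per-second pause rate scaled to one
    ``fragment_s``-second fragment.
    """
    out = {}
    for group, row in _TABLE.items():
        ms, ss, ws = row["short"]
        ml, sl, wl = row["long"]
        out[group] = GroupProfile(
            group=group,
            short=GaussianComponent(ms, ss, ws, LINEAR_MS),
            long=GaussianComponent(ml, sl, wl, LINEAR_MS),
            rate_mu=row["pause_rate_per_s"] * fragment_s,
            rate_beta=rate_beta,
            target_proportion_silence=row["proportion_silence"],
        )
    return out
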