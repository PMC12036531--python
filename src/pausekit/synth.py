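"""Synthetic speech-fluency cohorts.

Generates speakers in three groups (control, nfvPPA, svPPA) whose narrations
decompose into alternating speech and pause intervals with the statistical
structure the analysis pipeline assumes: pause durations follow the group's
two-component Gaussian mixture (floored at 50 ms), per-fragment pause counts
follow a Gamma-Poisson law, and optional audio renders each fragment as
band-limited noise so the voice activity detector can be exercised end to
end without any real recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .profiles import (
    FRAGMENT_S,
    LINEAR_MS,
    LOG10_MS,
    MIN_PAUSE_MS,
    GaussianComponent,
    GroupProfile,
    default_group_profiles,
)
from .segments import PAUSE, SPEECH, Interval, SegmentSequence


class GenerationError(RuntimeError):
    """Raised when a fragment cannot be synthesised within the retry budget."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# pause durations
# ---------------------------------------------------------------------------

def _component_draw(
    rng: np.random.Generator, comp: GaussianComponent, n: int, min_ms: float
) -> np.ndarray:
    """Draw ``n`` durations (ms) from one component, rejecting values < min_ms.

    The component identity is kept across rejections, so the mixture's
    membership fractions equal the nominal weights exactly and each
    component is a left-truncated Gaussian.
    """
    out = np.empty(n)
    pending = np.arange(n)
    for _ in range(10_000):
        if pending.size == 0:
            return out
        draw = rng.normal(comp.mean, comp.sd, size=pending.size)
        if comp.domain == LOG10_MS:
            draw = 10.0 ** draw
        ok = draw >= min_ms
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    raise GenerationError(
        f"component (mean={comp.mean}, sd={comp.sd}) rarely exceeds the "
        f"{min_ms} ms floor; cannot sample"
    )


def sample_pause_durations(
    profile: GroupProfile,
    n: int,
    seed=None,
    *,
    min_ms: float = MIN_PAUSE_MS,
    return_components: bool = False,
):
    """Sample ``n`` pause durations (ms) from a group's duration mixture.

    A component is chosen by its mixing weight, then the duration is drawn
    from that component's Gaussian (in the profile's domain) and redrawn
    until it reaches ``min_ms`` — the same floor the pause detector applies.

    Returns the durations, and with ``return_components=True`` also a
    boolean array marking draws from the long component.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(profile, GroupProfile):
        raise ValueError("profile must be a GroupProfile")
    rng = _as_rng(seed)
    is_long = rng.random(n) < profile.long.weight
    out = np.empty(n)
    n_long = int(is_long.sum())
    if n_long:
        out[is_long] = _component_draw(rng, profile.long, n_long, min_ms)
    if n - n_long:
        out[~is_long] = _component_draw(rng, profile.short, n - n_long, min_ms)
    if return_components:
        return out, is_long
    return out


def sample_pause_count(profile: GroupProfile, rng: np.random.Generator, size=None):
    """Draw pause counts from Gamma-Poisson(rate_mu, rate_beta)."""
    if profile.rate_mu == 0:
        return np.zeros(size, dtype=int) if size is not None else 0
    lam = rng.gamma(shape=profile.rate_beta, scale=profile.rate_mu / profile.rate_beta, size=size)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

_MAX_FRAGMENT_RETRIES = 100
_MIN_SPEECH_CHUNK_S = 1e-3


def sample_fragment(
    profile: GroupProfile,
    fragment_s: float = FRAGMENT_S,
    seed=None,
    *,
    max_silence_fraction: float = 0.95,
) -> SegmentSequence:
    """Synthesise one fragment of exactly ``fragment_s`` seconds.

    The pause count is Gamma-Poisson, pause durations come from
    :func:`sample_pause_durations`, and the remaining speech time is split
    uniformly at random into the runs between pauses.  Draws whose total
    silence exceeds ``max_silence_fraction`` of the fragment are redrawn.
    """
    if not fragment_s > 0:
        raise ValueError("fragment_s must be > 0")
    rng = _as_rng(seed)
    for _ in range(_MAX_FRAGMENT_RETRIES):
        k = int(sample_pause_count(profile, rng))
        if k == 0:
            return SegmentSequence([(0.0, fragment_s, SPEECH)])
        pauses_s = sample_pause_durations(profile, k, rng) / 1000.0
        if pauses_s.sum() > max_silence_fraction * fragment_s:
            continue
        speech_total = fragment_s - pauses_s.sum()
        # uniform random split of the speech time into k+1 positive runs
        for _ in range(100):
            cuts = np.sort(rng.random(k)) * speech_total
            chunks = np.diff(np.concatenate([[0.0], cuts, [speech_total]]))
            if chunks.min() > _MIN_SPEECH_CHUNK_S:
                break
        else:  # pragma: no cover - probability ~0
            continue
        durations: list[float] = []
        labels: list[str] = []
        for i in range(k):
            durations += [chunks[i], pauses_s[i]]
            labels += [SPEECH, PAUSE]
        durations.append(chunks[k])
        labels.append(SPEECH)
        seq = SegmentSequence.from_durations(durations, labels)
        # pin the exact total against float accumulation
        last = seq.intervals[-1]
        ivs = list(seq.intervals[:-1]) + [Interval(last.start, fragment_s, last.label)]
        return SegmentSequence(ivs)
    raise GenerationError(
        f"could not fit sampled pauses (mu={profile.rate_mu}) into a "
        f"{fragment_s:.1f} s fragment after {_MAX_FRAGMENT_RETRIES} attempts"
    )


# ---------------------------------------------------------------------------
# audio rendering
# ---------------------------------------------------------------------------

def render_audio(
    segments: SegmentSequence,
    sample_rate: int = 16_000,
    seed=None,
    *,
    speech_rms: float = 0.1,
    snr_db: float = 30.0,
    band_hz: tuple[float, float] = (300.0, 3400.0),
) -> np.ndarray:
    """Render a segment sequence as band-limited noise.

    Speech intervals carry noise at ``speech_rms``; pause intervals carry
    the same noise attenuated by ``snr_db`` decibels.  The result is a
    float waveform of ``round(duration * sample_rate)`` samples.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    rng = _as_rng(seed)
    n = int(round(segments.duration * sample_rate))
    noise = rng.standard_normal(n)
    sos = signal.butter(4, band_hz, btype="bandpass", fs=sample_rate, output="sos")
    noise = signal.sosfiltfilt(sos, noise)
    noise /= np.sqrt(np.mean(noise**2))
    envelope = np.full(n, speech_rms * 10.0 ** (-snr_db / 20.0))
    for iv in segments:
        if iv.label == SPEECH:
            a = int(round(iv.start * sample_rate))
            b = int(round(iv.end * sample_rate))
            envelope[a:b] = speech_rms
    return noise * envelope


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Speaker:
    speaker_id: str
    group: str
    moments: int


@dataclass
class CohortDataset:
    """A synthetic cohort: speakers, their fragment sequences and provenance.

    ``sequences`` maps ``(speaker_id, moment)`` to the list of 20-s fragment
    sequences for that elicitation moment.  ``manifest`` records every
    generating parameter including the master seed.
    """

    speakers: list[Speaker]
    sequences: dict[tuple[str, int], list[SegmentSequence]]
    manifest: dict

    def iter_fragments(self) -> Iterator[tuple[Speaker, int, int, SegmentSequence]]:
        for sp in self.speakers:
            for moment in range(sp.moments):
                for frag_id, seq in enumerate(self.sequences[(sp.speaker_id, moment)]):
                    yield sp, moment, frag_id, seq

    def to_interval_frame(self) -> pd.DataFrame:
        rows = []
        for sp, moment, frag_id, seq in self.iter_fragments():
            for iv in seq:
                rows.append(
                    (sp.speaker_id, sp.group, moment, frag_id, iv.start, iv.end, iv.label)
                )
        return pd.DataFrame(
            rows,
            columns=["speaker_id", "group", "moment", "fragment_id", "start_s", "end_s", "label"],
        )

    def pause_table(self, min_pause_ms: float = MIN_PAUSE_MS) -> pd.DataFrame:
        """Per-pause records across the cohort (one row per pause >= floor)."""
        rows = []
        for sp, moment, frag_id, seq in self.iter_fragments():
            for iv in seq.pauses:
                dur = iv.duration * 1000.0
                if dur >= min_pause_ms - 1e-9:
                    rows.append((sp.speaker_id, sp.group, moment, frag_id, dur))
        return pd.DataFrame(
            rows, columns=["speaker_id", "group", "moment", "fragment_id", "duration_ms"]
        )

    def fragment_roster(self) -> pd.DataFrame:
        rows = [
            (sp.speaker_id, sp.group, moment, frag_id, seq.duration)
            for sp, moment, frag_id, seq in self.iter_fragments()
        ]
        return pd.DataFrame(
            rows, columns=["speaker_id", "group", "moment", "fragment_id", "duration_s"]
        )


def generate_cohort(
    n_per_group: Mapping[str, int] | Sequence[int] = (14, 7, 8),
    fragments_per_speaker: int = 5,
    moments: int = 1,
    seed=None,
    *,
    profiles: Mapping[str, GroupProfile] | None = None,
    fragment_s: float = FRAGMENT_S,
) -> CohortDataset:
    """Generate a deterministic synthetic cohort.

    ``n_per_group`` is either a mapping ``group -> count`` or a triple in
    the order (control, nfvPPA, svPPA); the default mirrors the study's
    14/7/8 participants.  Per-speaker random streams are spawned from the
    master seed, so cohorts are reproducible and speakers are independent.
    """
    if profiles is None:
        profiles = default_group_profiles()
    if not isinstance(n_per_group, Mapping):
        n_per_group = dict(zip(profiles.keys(), n_per_group, strict=True))
    if fragments_per_speaker < 1 or moments < 1:
        raise ValueError("fragments_per_speaker and moments must be >= 1")
    if any(n < 1 for n in n_per_group.values()):
        raise ValueError("every group needs at least one speaker")

    master = np.random.SeedSequence(seed)
    speakers: list[Speaker] = []
    sequences: dict[tuple[str, int], list[SegmentSequence]] = {}
    idx = 0
    child_seeds = master.spawn(sum(n_per_group.values()))
    for group, n_speakers in n_per_group.items():
        profile = profiles[group]
        for s in range(n_speakers):
            sid = f"{group}-{s + 1:02d}"
            sp = Speaker(sid, group, moments)
            speakers.append(sp)
            rng = np.random.default_rng(child_seeds[idx])
            idx += 1
            for moment in range(moments):
                sequences[(sid, moment)] = [
                    sample_fragment(profile, fragment_s, rng)
                    for _ in range(fragments_per_speaker)
                ]
    manifest = {
        "seed": seed,
        "n_per_group": dict(n_per_group),
        "fragments_per_speaker": fragments_per_speaker,
        "moments": moments,
        "fragment_s": fragment_s,
        "profiles": {
            g: {
                "short": vars(p.short).copy(),
                "long": vars(p.long).copy(),
                "rate_mu": p.rate_mu,
                "rate_beta": p.rate_beta,
                "target_proportion_silence": p.target_proportion_silence,
            }
            for g, p in profiles.items()
        },
    }
    return CohortDataset(speakers=speakers, sequences=sequences, manifest=manifest)
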