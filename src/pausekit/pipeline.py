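"""End-to-end pipeline: synthesis/ingest -> segmentation -> metrics ->
mixture -> rate model -> classifier, with a reproducible run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import fit_group_classifier, grouped_cv_accuracy
from .io import (
    read_interval_table,
    sequences_from_interval_table,
    write_interval_table,
    write_pause_table,
    write_textgrid,
    write_wav,
)
from .metrics import fluency_frame, group_anova, icc1, kruskal_wallis, permanova
from .mixture import NoCrossingError, fit_pause_mixture
from .rates import (
    RatePriors,
    build_count_table,
    fit_rate_model,
    group_mu_difference,
    posterior_predictive_check,
)
from .synth import generate_cohort, render_audio
from .vad import detect_speech, segments_from_labels


class PipelineError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    All randomness flows from ``seed``; every stage derives its own stream
    from it.  ``input_intervals`` may point at an interval-table CSV to
    analyse recorded (or previously segmented) data instead of synthesising
    a cohort.
    """

    out_dir: str = "pausekit_run"
    seed: int = 0
    # synthesis
    n_per_group: tuple = (14, 7, 8)
    fragments_per_speaker: int = 5
    moments: int = 1
    write_audio: bool = False
    # ingest instead of synthesis
    input_intervals: str | None = None
    # audio / VAD roundtrip
    use_audio: bool = False
    sample_rate: int = 16_000
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    threshold_quantile: float | None = None
    hangover_ms: float = 0.0
    # segmentation
    fragment_s: float = 20.0
    min_pause_ms: float = 50.0
    min_speech_ms: float = 50.0
    # mixture
    mixture_k: int = 2
    mixture_starts: int = 8
    mixture_tol: float = 1e-8
    mixture_max_iter: int = 500
    cutoff_group: str = "control"
    # rate model
    n_chains: int = 2
    n_iter: int = 4000
    hdi_mass: float = 0.89
    rate_classes: tuple = ("short", "long")
    # classifier
    cv_splits: int = 5
    # stage toggles
    run_metrics: bool = True
    run_mixture: bool = True
    run_rates: bool = True
    run_classifier: bool = True

    def validate(self) -> None:
        if self.fragment_s <= 0:
            raise ValueError("fragment_s must be > 0")
        if self.min_pause_ms <= 0 or self.min_speech_ms <= 0:
            raise ValueError("duration floors must be > 0")
        if self.mixture_k < 1:
            raise ValueError("mixture_k must be >= 1")
        if self.n_chains < 1 or self.n_iter < 100:
            raise ValueError("rate model needs >= 1 chain and >= 100 iterations")
        if not 0 < self.hdi_mass < 1:
            raise ValueError("hdi_mass must be in (0, 1)")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group entries must be >= 1")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        if isinstance(cfg.n_per_group, list):
            cfg.n_per_group = tuple(cfg.n_per_group)
        if isinstance(cfg.rate_classes, list):
            cfg.rate_classes = tuple(cfg.rate_classes)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    versions: dict
    started: str
    finished: str = ""
    stages: list = field(default_factory=list)
    hashes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    metrics: pd.DataFrame | None = None
    group_stats: dict | None = None
    mixture_fits: dict | None = None
    cutoff_ms: float | None = None
    count_table: pd.DataFrame | None = None
    posterior: object | None = None
    contrasts: pd.DataFrame | None = None
    ppc: dict | None = None
    classifier_accuracy: float | None = None
    report: dict | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str), encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write all outputs to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        versions={
            "pausekit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    result = PipelineResult(manifest=manifest)
    completed: list[str] = []
    report: dict = {}
    stage = "setup"
    try:
        # ---------------- data ------------------------------------------
        stage = "synth"
        if config.input_intervals:
            frame = read_interval_table(config.input_intervals)
            tagged = [
                (dict(zip(["speaker_id", "group", "moment", "fragment_id"], key)), seq)
                for key, seq in sequences_from_interval_table(frame)
            ]
        else:
            cohort = generate_cohort(
                config.n_per_group,
                config.fragments_per_speaker,
                config.moments,
                seed=config.seed,
                fragment_s=config.fragment_s,
            )
            tagged = [
                (
                    {
                        "speaker_id": sp.speaker_id,
                        "group": sp.group,
                        "moment": moment,
                        "fragment_id": frag_id,
                    },
                    seq,
                )
                for sp, moment, frag_id, seq in cohort.iter_fragments()
            ]
            write_interval_table(cohort.to_interval_frame(), out / "intervals.csv")
            if config.write_audio:
                audio_dir = out / "audio"
                audio_dir.mkdir(exist_ok=True)
                rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
                for meta, seq in tagged:
                    name = f"{meta['speaker_id']}_m{meta['moment']}_f{meta['fragment_id']}"
                    wav = render_audio(seq, config.sample_rate, rng)
                    write_wav(audio_dir / f"{name}.wav", wav, config.sample_rate)
                    write_textgrid(audio_dir / f"{name}.TextGrid", seq)
        completed.append("synth")

        # ---------------- segmentation (optional audio roundtrip) -------
        stage = "segment"
        if config.use_audio and not config.input_intervals:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
            resegmented = []
            for meta, seq in tagged:
                wav = render_audio(seq, config.sample_rate, rng)
                labels = detect_speech(
                    wav,
                    config.sample_rate,
                    config.frame_ms,
                    config.hop_ms,
                    config.threshold_quantile,
                    config.hangover_ms,
                )
                resegmented.append(
                    (meta, segments_from_labels(labels, config.min_pause_ms, config.min_speech_ms))
                )
            tagged = resegmented
        completed.append("segment")

        # ---------------- pause table -----------------------------------
        stage = "pauses"
        rows = []
        for meta, seq in tagged:
            for iv in seq.pauses:
                dur = iv.duration * 1000.0
                if dur >= config.min_pause_ms - 1e-9:
                    rows.append({**meta, "duration_ms": dur})
        pauses = pd.DataFrame(
            rows, columns=["speaker_id", "group", "moment", "fragment_id", "duration_ms"]
        )
        if pauses.empty:
            raise RuntimeError("no pauses found in any fragment")
        write_pause_table(pauses, out / "pauses.csv")
        roster = pd.DataFrame([m for m, _ in tagged])
        completed.append("pauses")

        # ---------------- fluency metrics -------------------------------
        if config.run_metrics:
            stage = "metrics"
            metrics = fluency_frame(tagged)
            metrics.to_csv(out / "metrics.csv", index=False)
            result.metrics = metrics
            per_sample = (
                metrics.groupby(["speaker_id", "group", "moment"], as_index=False)
                .agg(
                    locution_time_s=("locution_time_s", "sum"),
                    phonation_time_s=("phonation_time_s", "sum"),
                    silence_time_s=("silence_time_s", "sum"),
                    n_pauses=("n_pauses", "sum"),
                )
            )
            per_sample["pause_rate"] = per_sample["n_pauses"] / per_sample["phonation_time_s"]
            per_sample["proportion_silence"] = (
                per_sample["silence_time_s"] / per_sample["locution_time_s"]
            )
            stats = {}
            for var in ("phonation_time_s", "locution_time_s", "pause_rate", "proportion_silence"):
                res = group_anova(per_sample[var], per_sample["group"])
                perm = permanova(
                    per_sample[[var]].to_numpy(),
                    per_sample["group"].to_numpy(),
                    n_perm=999,
                    seed=config.seed,
                )
                stats[var] = {
                    "group_means": per_sample.groupby("group")[var].mean().to_dict(),
                    "anova_F": res.statistic,
                    "anova_df": list(res.df),
                    "anova_p": res.p_value,
                    "contrasts": res.contrasts.to_dict(orient="records"),
                    "permanova_F": perm.statistic,
                    "permanova_p": perm.p_value,
                }
            stats["icc1_pause_rate"] = icc1(per_sample["pause_rate"], per_sample["speaker_id"])
            result.group_stats = stats
            report["fluency"] = stats
            _write_json(out / "group_stats.json", stats)
            completed.append("metrics")

        # ---------------- mixture ----------------------------------------
        cutoff = None
        if config.run_mixture:
            stage = "mixture"
            fits = {}
            for g, sub in pauses.groupby("group"):
                fits[g] = fit_pause_mixture(
                    sub["duration_ms"].to_numpy(),
                    k=config.mixture_k,
                    n_starts=config.mixture_starts,
                    tol=config.mixture_tol,
                    max_iter=config.mixture_max_iter,
                    seed=config.seed,
                )
            result.mixture_fits = fits
            ref = fits.get(config.cutoff_group) or next(iter(fits.values()))
            try:
                cutoff = ref.cutoff_ms()
            except NoCrossingError:
                cutoff = None
            result.cutoff_ms = cutoff
            report["mixture"] = {
                "cutoff_ms": cutoff,
                "cutoff_group": config.cutoff_group,
                "fits": {g: f.to_dict() for g, f in fits.items()},
                "lambda_long_by_group": {g: f.lambda_long for g, f in fits.items()},
            }
            _write_json(out / "mixture.json", report["mixture"])
            completed.append("mixture")

        # ---------------- rate model -------------------------------------
        if config.run_rates:
            stage = "rates"
            if cutoff is None:
                raise RuntimeError("rate stage needs a cutoff from the mixture stage")
            table = build_count_table(pauses, cutoff, roster)
            table.to_csv(out / "counts.csv", index=False)
            result.count_table = table
            posterior = fit_rate_model(
                table,
                n_chains=config.n_chains,
                n_iter=config.n_iter,
                seed=config.seed,
                classes=config.rate_classes,
            )
            result.posterior = posterior
            summary = posterior.summary(config.hdi_mass)
            summary.to_csv(out / "posterior_summary.csv", index=False)
            groups = list(pd.unique(roster["group"]))
            rows = []
            for cls in config.rate_classes:
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        diff = group_mu_difference(
                            posterior, groups[i], groups[j], cls, config.hdi_mass
                        )
                        rows.append(
                            {
                                "pause_class": cls,
                                "group_a": groups[i],
                                "group_b": groups[j],
                                "mean_difference": float(diff.samples.mean()),
                                "hdi_lower": diff.hdi.lower,
                                "hdi_upper": diff.hdi.upper,
                                "excludes_zero": diff.excludes_zero,
                            }
                        )
            contrasts = pd.DataFrame(rows)
            contrasts.to_csv(out / "contrasts.csv", index=False)
            result.contrasts = contrasts
            ppc = {
                cls: {
                    g: r.tv_distance
                    for g, r in posterior_predictive_check(
                        posterior[cls], table, seed=config.seed
                    ).items()
                }
                for cls in config.rate_classes
            }
            result.ppc = ppc
            report["rates"] = {
                "posterior_summary": summary.to_dict(orient="records"),
                "contrasts": rows,
                "ppc_tv_distance": ppc,
            }
            completed.append("rates")

        # ---------------- classifier -------------------------------------
        if config.run_classifier:
            stage = "classify"
            feats = _fragment_features(result, pauses, roster, cutoff)
            acc = grouped_cv_accuracy(
                feats.drop(columns=["speaker_id", "group"]).to_numpy(),
                feats["group"].to_numpy(),
                feats["speaker_id"].to_numpy(),
                n_splits=config.cv_splits,
                seed=config.seed,
            )
            result.classifier_accuracy = acc
            report["classifier"] = {
                "grouped_cv_accuracy": acc,
                "n_fragments": int(len(feats)),
                "chance_level": 1.0 / feats["group"].nunique(),
            }
            completed.append("classify")

        report["qualitative_summary"] = _qualitative_summary(result)
        result.report = report
        _write_json(out / "report.json", report)
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.stages = completed
        for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
            if f.name != "manifest.json":
                manifest.hashes[f.name] = _sha256(f)
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        return result
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, completed, exc) from exc


def _fragment_features(result, pauses, roster, cutoff) -> pd.DataFrame:
    """Fragment-level feature matrix for the group classifier."""
    if result.metrics is None:
        raise RuntimeError("classifier stage needs the metrics stage")
    feats = result.metrics[
        ["speaker_id", "group", "moment", "fragment_id",
         "proportion_silence", "pause_rate", "n_pauses", "avg_pause_len_ms"]
    ].copy()
    feats["avg_pause_len_ms"] = feats["avg_pause_len_ms"].fillna(0.0)
    feats["pause_rate"] = feats["pause_rate"].fillna(0.0)
    if result.count_table is not None:
        wide = result.count_table.pivot_table(
            index=["speaker_id", "moment", "fragment_id"],
            columns="pause_class",
            values="count",
        ).reset_index()
        feats = feats.merge(wide, on=["speaker_id", "moment", "fragment_id"], how="left")
        for cls in ("short", "long"):
            if cls in feats:
                feats[cls] = feats[cls].fillna(0.0)
    return feats.drop(columns=["moment", "fragment_id"])


def _qualitative_summary(result: PipelineResult) -> list[dict]:
    """Directional findings table (variable x group pair -> direction)."""
    rows = []
    if result.group_stats:
        for var in ("proportion_silence", "pause_rate"):
            means = result.group_stats[var]["group_means"]
            for a in means:
                for b in means:
                    if a < b:
                        rows.append(
                            {
                                "variable": var,
                                "pair": f"{a} vs {b}",
                                "direction": "higher" if means[a] > means[b] else "lower",
                            }
                        )
    if result.contrasts is not None:
        for rec in result.contrasts.to_dict(orient="records"):
            rows.append(
                {
                    "variable": f"rate of {rec['pause_class']} pauses",
                    "pair": f"{rec['group_a']} vs {rec['group_b']}",
                    "direction": (
                        ("more" if rec["mean_difference"] > 0 else "fewer")
                        if rec["excludes_zero"]
                        else "no difference"
                    ),
                }
            )
    return rows
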