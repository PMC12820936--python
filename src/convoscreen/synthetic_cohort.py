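"""Synthetic cohorts of remote-interview participants.

Real remote-interview recordings of older adults are identifiable and
access-restricted, so every downstream stage of this package is exercised
on virtual participants instead. A participant is a set of latent
construct severities (cognition, social connectedness, neuroticism, and
three emotional-wellbeing composites) tied together by one shared factor,
from which the generator derives

* clinical and psychosocial assessment scores calibrated to published
  cohort marginals (MoCA 24.54 +/- 3.61, LSNS-6 14.13 +/- 5.86, ...),
* sensitive attributes (sex, integer age, years of education, NC/MCI
  diagnosis),
* multimodal feature streams with label-dependent temporal structure:
  regime-switching Gaussian emissions whose state occupancies and means
  shift with the latent severity by a configurable effect size,
* a quasi-periodic pulse waveform whose mean heart rate shifts with
  severity, plus the 1 Hz BPM stream spectrally estimated from it,
* one high-dimensional static text embedding.

Ground-truth state paths and per-second heart rates are retained on each
record for oracle checks only; they are never part of the feature surface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .temporal_features import FeatureTimeSeries, estimate_bpm_series

__all__ = [
    "CohortConfig",
    "SensitiveAttributes",
    "AssessmentScores",
    "ParticipantRecord",
    "PulseWaveform",
    "generate_cohort",
    "generate_markov_stream",
    "generate_pulse_waveform",
    "save_cohort",
    "load_cohort",
    "CONSTRUCTS",
]

CONSTRUCTS = (
    "cognition",
    "social",
    "neuroticism",
    "negative_affect",
    "social_satisfaction",
    "psych_wellbeing",
)

#: Published cohort marginals used to calibrate the score generator:
#: (mean, sd) of the combined NC+MCI group per instrument.
SCORE_CALIBRATION = {
    "moca": (24.54, 3.61),
    "lsns6": (14.13, 5.86),
    "neuroticism": (16.44, 8.41),
    "negative_affect": (48.57, 10.93),
    "social_satisfaction": (49.02, 11.77),
    "psych_wellbeing": (50.87, 9.99),
}

DEFAULT_MODALITY_DIMS = {
    "emotion_aus": 24,
    "facial_embedding": 1024,
    "acoustic": 34,
    "speech_embedding": 768,
    "sentiment": 9,
    "bpm": 1,
    "text_embedding": 8192,  # static, one vector per participant
}

# Default stream rates in Hz. Facial sets at 1 Hz and acoustic statistics at
# 10 Hz follow the extraction cadence they emulate; the speech-embedding
# default is kept at 5 Hz so a full default cohort stays within ordinary
# workstation memory (the cadence only changes frame counts, not the
# participant-level aggregation targets), and is configurable.
DEFAULT_SAMPLING_RATES = {
    "emotion_aus": 1.0,
    "facial_embedding": 1.0,
    "acoustic": 10.0,
    "speech_embedding": 5.0,
    "sentiment": 1.0 / 15.0,  # utterance-level, ~one utterance per 15 s
    "bpm": 1.0,
}

#: Which latent construct drives each feature stream's dynamics.
DEFAULT_STREAM_CONSTRUCTS = {
    "emotion_aus": "cognition",
    "facial_embedding": "psych_wellbeing",
    "acoustic": "negative_affect",
    "speech_embedding": "cognition",
    "sentiment": "social",
    "bpm": "psych_wellbeing",
    "text_embedding": "cognition",
}

_N_STATES = 4
_STICKINESS = 0.88
_STATE_SCORE = np.array([-1.5, -0.5, 0.5, 1.5])


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the standardized shift of stream dynamics per unit
    of latent severity: it scales both the state-occupancy bias and the
    emission mean shift. A scalar applies to every stream; a mapping sets
    per-stream effects (missing streams get 0).
    """

    n_participants: int = 39
    seed: int = 0
    effect_size: float | Mapping[str, float] = 1.0
    length_range_min: tuple[float, float] = (25.0, 47.0)
    modality_dims: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_DIMS)
    )
    sampling_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_RATES)
    )
    stream_constructs: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STREAM_CONSTRUCTS)
    )
    group_probs: Mapping[str, float] = field(
        default_factory=lambda: {"sex_F": 29.0 / 39.0}
    )
    #: shared-factor loading of each construct severity
    factor_loading: float = 0.5
    #: correlation between a latent severity and its noisy assessment score
    score_reliability: float = 0.9
    #: optional label confound: log-odds shift added for the flagged group
    bias_attribute: str | None = None
    bias_strength: float = 0.0
    emission_sd: float = 1.0
    state_separation: float = 1.0

    def validate(self) -> None:
        if self.n_participants < 5:
            raise ValueError("cohort needs at least 5 participants (one per fold)")
        for name, d in self.modality_dims.items():
            if d <= 0:
                raise ValueError(f"feature set {name!r} has non-positive dimension")
        for name, r in self.sampling_rates.items():
            if r <= 0:
                raise ValueError(f"feature set {name!r} has non-positive rate")
        lo, hi = self.length_range_min
        if not (0 < lo <= hi):
            raise ValueError("invalid interview length range")

    def effect_for(self, feature_set: str) -> float:
        if isinstance(self.effect_size, Mapping):
            return float(self.effect_size.get(feature_set, 0.0))
        return float(self.effect_size)


@dataclass
class SensitiveAttributes:
    """Demographics and diagnosis used for fairness grouping."""

    sex: str  # {"F", "M"}
    age_years: int
    yoe: int
    diagnosis: str  # {"NC", "MCI"}

    @property
    def age_group(self) -> str:
        # median split of the emulated cohort
        return "<=78.9" if self.age_years <= 78.9 else ">78.9"

    @property
    def yoe_group(self) -> str:
        if self.yoe <= 15:
            return "below_college"
        if self.yoe == 16:
            return "college_graduate"
        return "graduate_plus"


@dataclass
class AssessmentScores:
    moca: int  # 0-30
    cdr: float  # {0.0, 0.5}
    lsns6: int  # 0-30
    neuroticism: int  # 0-48 (NEO-FFI facet sum)
    negative_affect: float
    social_satisfaction: float
    psych_wellbeing: float


@dataclass
class ParticipantRecord:
    participant_id: str
    attrs: SensitiveAttributes
    latent: dict[str, float]  # construct -> severity in [0, 1]
    scores: AssessmentScores
    streams: dict[str, FeatureTimeSeries]
    static_vectors: dict[str, np.ndarray]
    #: oracle-only channel (true state paths, true BPM); never featurized
    ground_truth: dict[str, np.ndarray] = field(default_factory=dict)
    interview_len_s: float = 0.0


@dataclass
class PulseWaveform:
    samples: np.ndarray
    fs: float
    true_bpm: np.ndarray  # per-second ground truth


# ---------------------------------------------------------------------------
# low-level generators
# ---------------------------------------------------------------------------

def generate_markov_stream(
    n_states: int,
    transition: np.ndarray,
    emission_means: np.ndarray,
    emission_sd: float,
    length: int,
    seed: int,
    rate: float = 1.0,
    start_probs: np.ndarray | None = None,
    feature_set: str = "",
) -> tuple[FeatureTimeSeries, np.ndarray]:
    """Sample a Gaussian regime-switching stream and its true state path.

    Returns ``(series, state_path)``; the path is the oracle channel for
    occupancy checks and is not part of the series.
    """
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (n_states, n_states) or np.any(transition < 0):
        raise ValueError("transition must be a nonnegative square matrix")
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    emission_means = np.atleast_2d(np.asarray(emission_means, dtype=float))
    if emission_means.shape[0] != n_states:
        raise ValueError("one emission mean row per state required")
    if length < 1:
        raise ValueError("length must be at least one frame")
    rng = np.random.default_rng(seed)
    if start_probs is None:
        start_probs = np.full(n_states, 1.0 / n_states)
    path = np.empty(length, dtype=np.int64)
    path[0] = rng.choice(n_states, p=start_probs)
    cum = np.cumsum(transition, axis=1)
    u = rng.random(length)
    for t in range(1, length):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    values = emission_means[path]
    if emission_sd > 0:
        values = values + rng.normal(0.0, emission_sd, size=values.shape)
    series = FeatureTimeSeries(values=values, rate=rate, feature_set=feature_set)
    return series, path


def _sticky_chain(pi: np.ndarray, stickiness: float, length: int, rng) -> np.ndarray:
    """Path from the transition ``stick*I + (1-stick)*1 pi^T`` (stationary pi).

    Sampled in vectorized form: at each step the chain either stays or
    redraws from pi; the state at time t is the most recent redraw.
    """
    redraw = rng.random(length) >= stickiness
    redraw[0] = True
    draws = rng.choice(len(pi), size=length, p=pi)
    last = np.maximum.accumulate(np.where(redraw, np.arange(length), -1))
    return draws[last]


def generate_pulse_waveform(
    mean_bpm: float,
    bpm_jitter_sd: float,
    duration_s: float,
    fs: float,
    seed: int,
) -> PulseWaveform:
    """Quasi-periodic pulse signal with per-second frequency jitter.

    The instantaneous frequency over second ``t`` is
    ``(mean_bpm + jitter_t) / 60`` Hz; the jitter is a stationary AR(1)
    process (lag-1 correlation 0.95, stationary SD ``bpm_jitter_sd``),
    since heart rate drifts smoothly rather than jumping second to
    second. The phase integrates the frequency, and the waveform is a
    fundamental plus a small second harmonic (a crude pulse shape).
    Ground-truth per-second BPM is kept.
    """
    if not (30.0 <= mean_bpm <= 220.0):
        raise ValueError("mean BPM outside the 30-220 physiologic range")
    if fs < 2.0 * (mean_bpm / 60.0) * 2.0:
        raise ValueError("sampling rate undersamples the pulse fundamental")
    rng = np.random.default_rng(seed)
    n_sec = int(np.ceil(duration_s))
    if bpm_jitter_sd > 0:
        rho = 0.95
        innov = rng.normal(0.0, bpm_jitter_sd * np.sqrt(1 - rho**2), n_sec)
        jitter = np.empty(n_sec)
        jitter[0] = rng.normal(0.0, bpm_jitter_sd)
        for t in range(1, n_sec):
            jitter[t] = rho * jitter[t - 1] + innov[t]
        bpm = mean_bpm + jitter
    else:
        bpm = np.full(n_sec, mean_bpm)
    bpm = np.clip(bpm, 40.0, 200.0)
    n = int(round(duration_s * fs))
    t_idx = np.minimum((np.arange(n) / fs).astype(int), n_sec - 1)
    freq = bpm[t_idx] / 60.0
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    wave = np.sin(phase) + 0.3 * np.sin(2.0 * phase + 0.5)
    return PulseWaveform(samples=wave, fs=fs, true_bpm=bpm)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _stable_direction(name: str, tag: str, dim: int) -> np.ndarray:
    """Deterministic unit-RMS direction vector per (feature set, role)."""
    h = int.from_bytes(hashlib.sha256(f"{name}:{tag}".encode()).digest()[:4], "big")
    rng = np.random.default_rng(h)
    w = rng.normal(size=dim)
    return w / np.sqrt(np.mean(w**2))


def _latents(rng, cfg: CohortConfig) -> dict[str, float]:
    from scipy.stats import norm

    g = rng.normal()
    lam = cfg.factor_loading
    out: dict[str, float] = {"_factor": g}
    for c in CONSTRUCTS:
        z = lam * g + np.sqrt(1.0 - lam**2) * rng.normal()
        out[c] = z
    # severity on [0,1] for stream generation; raw z kept under "_z_" keys
    sev = {c: float(norm.cdf(out[c])) for c in CONSTRUCTS}
    sev.update({f"_z_{c}": float(out[c]) for c in CONSTRUCTS})
    sev["_factor"] = float(g)
    return sev


def _noisy(z: float, rho: float, rng) -> float:
    return rho * z + np.sqrt(1.0 - rho**2) * rng.normal()


def _scores(latent: dict[str, float], rng, cfg: CohortConfig) -> AssessmentScores:
    rho = cfg.score_reliability
    m, s = SCORE_CALIBRATION["moca"]
    moca = int(np.clip(round(m - s * _noisy(latent["_z_cognition"], rho, rng)), 0, 30))
    cdr = 0.5 if rng.random() < _sigmoid(2.0 * latent["_z_cognition"]) else 0.0
    m, s = SCORE_CALIBRATION["lsns6"]
    lsns = int(np.clip(round(m - s * _noisy(latent["_z_social"], rho, rng)), 0, 30))
    m, s = SCORE_CALIBRATION["neuroticism"]
    neuro = int(np.clip(round(m + s * _noisy(latent["_z_neuroticism"], rho, rng)), 0, 48))
    m, s = SCORE_CALIBRATION["negative_affect"]
    na = float(m + s * _noisy(latent["_z_negative_affect"], rho, rng))
    m, s = SCORE_CALIBRATION["social_satisfaction"]
    ss = float(m - s * _noisy(latent["_z_social_satisfaction"], rho, rng))
    m, s = SCORE_CALIBRATION["psych_wellbeing"]
    pw = float(m - s * _noisy(latent["_z_psych_wellbeing"], rho, rng))
    return AssessmentScores(moca, cdr, lsns, neuro, na, ss, pw)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _stream_for(
    name: str,
    dim: int,
    rate: float,
    severity: float,
    effect: float,
    length_s: float,
    cfg: CohortConfig,
    rng,
) -> tuple[FeatureTimeSeries, np.ndarray]:
    """One regime-switching stream whose dynamics encode the severity."""
    frames = max(int(round(length_s * rate)), 2)
    u = 2.0 * severity - 1.0  # centered severity in [-1, 1]
    logits = effect * u * _STATE_SCORE
    pi = np.exp(logits - logits.max())
    pi /= pi.sum()
    path = _sticky_chain(pi, _STICKINESS, frames, rng)
    w_state = _stable_direction(name, "state", dim)
    w_shift = _stable_direction(name, "shift", dim)
    means = np.outer(_STATE_SCORE * cfg.state_separation, w_state)
    base = 0.3 * effect * u * w_shift
    values = (means[path] + base).astype(np.float32)
    values += rng.normal(0.0, cfg.emission_sd, size=values.shape).astype(np.float32)
    series = FeatureTimeSeries(values=values, rate=rate, feature_set=name)
    return series, path


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate one cohort; identical config and seed give identical cohorts."""
    config.validate()
    root = np.random.default_rng(config.seed)
    # one independent child stream per participant keeps records stable
    # under changes to cohort size
    seeds = root.integers(0, 2**31 - 1, size=config.n_participants)
    records = []
    lo, hi = config.length_range_min
    for i in range(config.n_participants):
        rng = np.random.default_rng(seeds[i])
        sex = "F" if rng.random() < config.group_probs.get("sex_F", 0.5) else "M"
        age = int(np.clip(round(rng.normal(80.69, 4.6)), 75, 95))
        yoe = int(np.clip(round(rng.normal(15.44, 2.34)), 8, 22))
        latent = _latents(rng, config)
        if config.bias_attribute is not None and config.bias_strength != 0.0:
            flagged = {
                "sex": sex == "F",
                "age": age > 78.9,
                "yoe": yoe <= 15,
            }.get(config.bias_attribute, False)
            if flagged:
                shift = config.bias_strength
                for c in CONSTRUCTS:
                    latent[f"_z_{c}"] += shift
                    from scipy.stats import norm

                    latent[c] = float(norm.cdf(latent[f"_z_{c}"]))
        diagnosis = (
            "MCI"
            if rng.random() < _sigmoid(2.0 * latent["_z_cognition"] + 0.35)
            else "NC"
        )
        scores = _scores(latent, rng, config)
        length_s = float(rng.uniform(lo * 60.0, hi * 60.0))

        streams: dict[str, FeatureTimeSeries] = {}
        statics: dict[str, np.ndarray] = {}
        truth: dict[str, np.ndarray] = {}
        for name, dim in config.modality_dims.items():
            construct = config.stream_constructs.get(name, "cognition")
            sev = latent[construct]
            eff = config.effect_for(name)
            if name == "text_embedding":
                w = _stable_direction(name, "shift", dim)
                vec = 0.5 * eff * (2 * sev - 1) * w + rng.normal(size=dim)
                statics[name] = vec.astype(np.float32)
                continue
            if name == "bpm":
                mean_bpm = 72.0 + 6.0 * eff * (2 * sev - 1)
                pulse = generate_pulse_waveform(
                    mean_bpm=float(np.clip(mean_bpm, 45, 180)),
                    bpm_jitter_sd=3.0,
                    duration_s=length_s,
                    fs=30.0,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                bpm_est = estimate_bpm_series(pulse.samples, pulse.fs)
                streams[name] = FeatureTimeSeries(
                    values=bpm_est[:, None], rate=1.0, feature_set=name
                )
                truth["bpm_true"] = pulse.true_bpm
                continue
            rate = config.sampling_rates.get(name, 1.0)
            series, path = _stream_for(
                name, dim, rate, sev, eff, length_s, config, rng
            )
            streams[name] = series
            truth[f"{name}_state_path"] = path

        records.append(
            ParticipantRecord(
                participant_id=f"C{1000 + i:04d}",
                attrs=SensitiveAttributes(sex, age, yoe, diagnosis),
                latent=latent,
                scores=scores,
                streams=streams,
                static_vectors=statics,
                ground_truth=truth,
                interview_len_s=length_s,
            )
        )
    return records


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_cohort(records: list[ParticipantRecord], out_dir: str | Path,
                config: CohortConfig | None = None) -> Path:
    """Write a cohort directory: participants.csv, per-stream CSVs, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "sex": r.attrs.sex,
                "age_years": r.attrs.age_years,
                "yoe": r.attrs.yoe,
                "diagnosis": r.attrs.diagnosis,
                "interview_len_s": r.interview_len_s,
                "moca": r.scores.moca,
                "cdr": r.scores.cdr,
                "lsns6": r.scores.lsns6,
                "neuroticism": r.scores.neuroticism,
                "negative_affect": r.scores.negative_affect,
                "social_satisfaction": r.scores.social_satisfaction,
                "psych_wellbeing": r.scores.psych_wellbeing,
            }
        )
        for name, s in r.streams.items():
            df = pd.DataFrame(
                s.values, columns=[f"f_{j}" for j in range(s.dim)]
            )
            df.insert(0, "t_seconds", np.arange(s.n_frames) / s.rate)
            df.insert(0, "frame_index", np.arange(s.n_frames))
            df.to_csv(out / f"{r.participant_id}_{name}.csv", index=False)
        for name, v in r.static_vectors.items():
            pd.DataFrame({"f": v}).to_csv(
                out / f"{r.participant_id}_{name}.csv", index=False
            )
    pd.DataFrame(rows).to_csv(out / "participants.csv", index=False)
    manifest = {
        "n_participants": len(records),
        "feature_sets": sorted(
            set().union(*[set(r.streams) | set(r.static_vectors) for r in records])
        ),
    }
    if config is not None:
        cfg = asdict(config)
        cfg["effect_size"] = (
            dict(config.effect_size)
            if isinstance(config.effect_size, Mapping)
            else config.effect_size
        )
        cfg["length_range_min"] = list(config.length_range_min)
        for k in ("modality_dims", "sampling_rates", "stream_constructs",
                  "group_probs"):
            cfg[k] = dict(cfg[k])
        manifest["config"] = cfg
        manifest["seed"] = config.seed
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def load_cohort(in_dir: str | Path) -> list[ParticipantRecord]:
    """Load a cohort written by :func:`save_cohort` (oracle channels are
    not persisted, so loaded records carry empty ground truth)."""
    src = Path(in_dir)
    table = pd.read_csv(src / "participants.csv")
    with open(src / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    feature_sets = manifest["feature_sets"]
    cfg = manifest.get("config", {})
    rates = cfg.get("sampling_rates", DEFAULT_SAMPLING_RATES)
    records = []
    for _, row in table.iterrows():
        pid = row["participant_id"]
        streams, statics = {}, {}
        for name in feature_sets:
            path = src / f"{pid}_{name}.csv"
            if not path.exists():
                continue
            df = pd.read_csv(path)
            if "frame_index" in df.columns:
                vals = df.drop(columns=["frame_index", "t_seconds"]).to_numpy()
                streams[name] = FeatureTimeSeries(
                    values=vals,
                    rate=float(rates.get(name, 1.0)) if name != "bpm" else 1.0,
                    feature_set=name,
                )
            else:
                statics[name] = df["f"].to_numpy()
        records.append(
            ParticipantRecord(
                participant_id=pid,
                attrs=SensitiveAttributes(
                    row["sex"], int(row["age_years"]), int(row["yoe"]),
                    row["diagnosis"],
                ),
                latent={},
                scores=AssessmentScores(
                    int(row["moca"]), float(row["cdr"]), int(row["lsns6"]),
                    int(row["neuroticism"]), float(row["negative_affect"]),
                    float(row["social_satisfaction"]),
                    float(row["psych_wellbeing"]),
                ),
                streams=streams,
                static_vectors=statics,
                interview_len_s=float(row["interview_len_s"]),
            )
        )
    return records
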