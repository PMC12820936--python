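"""Fixed-length participant features from variable-length multimodal streams.

Remote-interview feature streams (facial emotion/AU series, acoustic
statistics, embeddings, beat-per-minute series) differ in length because
interviews run 25-47 minutes. This module turns each stream into a
fixed-length per-participant vector by one of four routes:

* statistical aggregation (per-dimension mean and standard deviation),
* state-dynamics summaries from a four-state Gaussian hidden Markov model
  fitted to all training participants jointly,
* spectral heart-rate estimation from a pulse waveform followed by
  quantile summarization,
* uniform temporal resampling to a fixed frame count for sequence models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM

__all__ = [
    "FeatureTimeSeries",
    "GroupHmm",
    "HmmSummaryFeatures",
    "aggregate_stats",
    "fit_group_hmm",
    "hmm_state_summary",
    "estimate_bpm_series",
    "hrv_quantile_features",
    "uniform_resample",
]

#: Physiologic heart-rate search band in Hz (39-240 beats per minute).
BPM_BAND_HZ = (0.65, 4.0)

#: Spectral window length and hop for heart-rate estimation, in seconds.
BPM_WINDOW_S = 6.0
BPM_HOP_S = 1.0


@dataclass
class FeatureTimeSeries:
    """One participant's stream for one feature set.

    values is a (frames, dim) float matrix sampled at ``rate`` Hz.
    """

    values: np.ndarray
    rate: float
    feature_set: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("stream must be a non-empty (frames, dim) matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("stream contains non-finite values")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate


@dataclass
class GroupHmm:
    """A four-state Gaussian HMM fitted jointly to all training streams.

    ``t_max`` records the longest training sequence (frames); with the
    default native-length fitting it is metadata only, used when the
    literal pad-to-``t_max`` recipe is requested.
    """

    model: GaussianHMM
    t_max: int
    n_states: int = 4
    padded: bool = False
    train_fingerprint: tuple = field(default_factory=tuple)

    @property
    def means(self) -> np.ndarray:
        return self.model.means_

    @property
    def transition(self) -> np.ndarray:
        return self.model.transmat_


@dataclass
class HmmSummaryFeatures:
    """Per-state occupancy summaries of one decoded stream.

    duration[k]  — fraction of native frames assigned to state k (sums to 1)
    frequency[k] — maximal runs of state k per 100 native frames
    """

    duration: np.ndarray
    frequency: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.duration, self.frequency])


# ---------------------------------------------------------------------------
# statistical aggregation
# ---------------------------------------------------------------------------

def aggregate_stats(series: FeatureTimeSeries) -> np.ndarray:
    """Per-dimension mean and population standard deviation, concatenated.

    Returns a length ``2 * dim`` vector: means first, then standard
    deviations (population convention, ddof=0).
    """
    v = series.values
    if v.shape[0] < 1:
        raise ValueError("empty series")
    return np.concatenate([v.mean(axis=0), v.std(axis=0, ddof=0)])


# ---------------------------------------------------------------------------
# group HMM fitting and state summaries
# ---------------------------------------------------------------------------

def fit_group_hmm(
    training_series: Sequence[FeatureTimeSeries],
    seed: int,
    n_states: int = 4,
    n_iter: int = 20,
    pad_to_tmax: bool = False,
) -> GroupHmm:
    """Fit one Gaussian HMM to all training participants' streams.

    K-means initialization of the state means, then exactly ``n_iter``
    EM iterations over the multi-sequence likelihood. Diagonal Gaussian
    emissions. By default sequences enter at native length; with
    ``pad_to_tmax`` every sequence is zero-padded to the longest training
    length first (the literal fixed-length recipe; padding injects a
    near-zero regime into the emissions, hence not the default).

    Raises ``ValueError`` on fewer than two series or mismatched
    dimensions, and ``RuntimeError`` with diagnostics if EM produces a
    non-finite likelihood.
    """
    if len(training_series) < 2:
        raise ValueError("need at least two training series")
    dims = {s.dim for s in training_series}
    if len(dims) != 1:
        raise ValueError(f"inconsistent stream dimensions: {sorted(dims)}")
    t_max = max(s.n_frames for s in training_series)

    if pad_to_tmax:
        seqs = []
        for s in training_series:
            pad = np.zeros((t_max - s.n_frames, s.dim))
            seqs.append(np.vstack([s.values, pad]))
    else:
        seqs = [s.values for s in training_series]
    X = np.vstack(seqs)
    lengths = [len(q) for q in seqs]

    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=n_iter,
        tol=-np.inf,  # run every EM iteration; no early convergence exit
        random_state=int(seed) % (2**31 - 1),
        init_params="stmc",  # k-means drives the means init inside hmmlearn
    )
    model.fit(X, lengths)
    history = np.asarray(model.monitor_.history)
    if history.size and not np.isfinite(history[-1]):
        raise RuntimeError(
            f"HMM EM diverged: log-likelihood history {history.tolist()}"
        )
    return GroupHmm(model=model, t_max=t_max, n_states=n_states, padded=pad_to_tmax)


def _run_counts(path: np.ndarray, n_states: int) -> np.ndarray:
    """Number of maximal constant runs of each state along a path."""
    starts = np.ones(len(path), dtype=bool)
    starts[1:] = path[1:] != path[:-1]
    return np.bincount(path[starts], minlength=n_states).astype(float)


def hmm_state_summary(
    model: GroupHmm,
    series: FeatureTimeSeries,
    posterior: bool = False,
) -> HmmSummaryFeatures:
    """State-dynamics summary of one stream under a fitted group HMM.

    The most-likely joint state path is decoded over the native-length
    sequence (with ``posterior=True`` duration is instead the mean
    posterior state mass; frequency still comes from the most-likely
    path). Duration is the fraction of frames in each state; frequency is
    the number of maximal runs of each state per 100 frames.
    """
    if series.n_frames < 1:
        raise ValueError("zero-length series")
    if series.dim != model.means.shape[1]:
        raise ValueError("series dimension does not match the model")
    v = series.values
    if model.padded and model.t_max > series.n_frames:
        v = np.vstack([v, np.zeros((model.t_max - series.n_frames, series.dim))])
    path = model.model.predict(v)
    path = path[: series.n_frames]  # summaries over the native prefix
    n = series.n_frames
    duration = np.bincount(path, minlength=model.n_states) / n
    if posterior:
        post = model.model.predict_proba(v)[:n]
        duration = post.mean(axis=0)
    frequency = _run_counts(path, model.n_states) * 100.0 / n
    return HmmSummaryFeatures(duration=duration, frequency=frequency)


# ---------------------------------------------------------------------------
# heart rate from a pulse waveform
# ---------------------------------------------------------------------------

def estimate_bpm_series(waveform: np.ndarray, fs: float) -> np.ndarray:
    """Windowed spectral heart-rate estimates from a pulse waveform.

    The power spectral density of each 6-second window (advanced one
    second at a time) is searched for its dominant frequency within the
    physiologic band of 0.65-4.0 Hz; that frequency, in beats per minute,
    is the window's estimate. The spectrum is zero-padded eightfold so the
    peak grid is finer than the raw 1/6 Hz resolution.
    """
    waveform = np.asarray(waveform, dtype=np.float64).ravel()
    win = int(round(BPM_WINDOW_S * fs))
    hop = int(round(BPM_HOP_S * fs))
    if len(waveform) < win:
        raise ValueError("waveform shorter than one 6-second window")
    nfft = int(2 ** np.ceil(np.log2(win * 8)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= BPM_BAND_HZ[0]) & (freqs <= BPM_BAND_HZ[1])
    if not band.any():
        raise ValueError("sampling rate too low for the physiologic band")
    hann = np.hanning(win)
    out = []
    for start in range(0, len(waveform) - win + 1, hop):
        seg = waveform[start : start + win]
        seg = (seg - seg.mean()) * hann
        psd = np.abs(np.fft.rfft(seg, n=nfft)) ** 2
        peak = freqs[band][np.argmax(psd[band])]
        out.append(peak * 60.0)
    return np.asarray(out)


def hrv_quantile_features(bpm_series: np.ndarray) -> np.ndarray:
    """5th, 25th, 50th, 75th and 95th quantiles of the BPM estimates.

    Linear interpolation between order statistics; the output is
    non-decreasing by construction.
    """
    bpm = np.asarray(bpm_series, dtype=np.float64).ravel()
    if bpm.size < 1:
        raise ValueError("empty BPM series")
    return np.quantile(bpm, [0.05, 0.25, 0.50, 0.75, 0.95], method="linear")


# ---------------------------------------------------------------------------
# uniform resampling for sequence models
# ---------------------------------------------------------------------------

def uniform_resample(series: FeatureTimeSeries, target_len: int) -> FeatureTimeSeries:
    """Temporally uniform frame selection down to ``target_len`` frames.

    Frame i of the output is input frame ``round(i * (frames-1) /
    (target_len-1))``; the first and last frames are always retained.
    Downsampling only: ``target_len`` must not exceed the native length.
    """
    n = series.n_frames
    if target_len > n:
        raise ValueError(f"target length {target_len} exceeds native length {n}")
    if target_len < 1:
        raise ValueError("target length must be positive")
    if target_len == 1:
        idx = np.array([0])
    else:
        idx = np.round(np.arange(target_len) * (n - 1) / (target_len - 1)).astype(int)
    return FeatureTimeSeries(
        values=series.values[idx],
        rate=series.rate * target_len / n,
        feature_set=series.feature_set,
    )
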