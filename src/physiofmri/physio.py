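"""Peripheral physiological signals: containers, preprocessing and derived series.

Covers the signal chain feeding physiological noise correction and
event-related autonomic analysis:

* pulse (PPG) peak detection and the cardiac phase,
* respiratory phase by amplitude-histogram equalization,
* respiration volume per time (RVT),
* pupil-diameter cleaning (blink interpolation, smoothing, rejection rule),
* skin-conductance filtering,
* synchronization of recordings to the scanner trigger train.

Conventions: cardiac phase lives in [0, 2*pi) and is zero at each detected
beat; respiratory phase lives in (-pi, pi] with the sign of the respiration
derivative; RVT is breath depth over breath period, non-negative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import interp1d

logger = logging.getLogger("physiofmri")

#: samples dropped at the start of a scan to avoid non-steady-state volumes
N_DISCARD_VOLUMES = 4
#: pupil recordings with at least this invalid-sample fraction are rejected
PUPIL_REJECT_FRACTION = 0.10
#: default smoothing window for pupil diameter, in samples
PUPIL_SMOOTH_SAMPLES = 100
#: skin conductance: rolling-median then moving-average window, in samples
SC_MEDIAN_SAMPLES = 150
SC_SMOOTH_SAMPLES = 250
#: number of amplitude-histogram bins for the respiratory phase transfer
RESP_PHASE_BINS = 100
#: refractory period between successive pulse peaks (s)
PPG_REFRACTORY_S = 0.3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhysioRecording:
    """Multichannel peripheral recording sampled at a common rate.

    Parameters
    ----------
    channels
        Mapping of channel name (``ppg``, ``respiration``, ``sc``) to a 1-D
        float array; all channels must have equal length.
    fs
        Sampling rate in Hz (500 Hz for the polygraph this models).
    trigger_times
        Scanner trigger (volume onset) times in seconds relative to the
        start of the recording; non-decreasing.
    t0
        Offset of scan time zero relative to the recording start (s);
        set by :func:`sync_to_scan`.
    """

    channels: dict[str, np.ndarray]
    fs: float
    trigger_times: np.ndarray
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(np.diff(self.trigger_times) < 0):
            raise ValueError("trigger_times must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in scan-aligned seconds (recording start minus t0)."""
        return np.arange(self.n_samples) / self.fs - self.t0


@dataclass
class PupilRecording:
    """Pupil diameter with per-sample validity flags.

    ``pd`` holds diameter samples (arbitrary units or mm — downstream
    analysis is ratio-to-baseline and therefore unit-free); ``valid`` marks
    samples the eye tracker deemed artifact-free.
    """

    pd: np.ndarray
    valid: np.ndarray
    fs: float
    trigger_times: np.ndarray
    t0: float = 0.0
    rejected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pd = np.asarray(self.pd, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if len(self.pd) != len(self.valid):
            raise ValueError("pd and valid must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.pd)

    @property
    def artifact_fraction(self) -> float:
        return float(np.mean(~self.valid))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs - self.t0


@dataclass
class PhaseSeries:
    """A phase signal evaluated at given times.

    ``kind`` is ``"cardiac"`` (phase in [0, 2*pi)) or ``"respiratory"``
    (phase in (-pi, pi]).
    """

    t: np.ndarray
    phase: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.kind not in ("cardiac", "respiratory"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("non-finite phase values")


@dataclass
class RvtSeries:
    """Respiration volume per time: breath depth / breath period.

    Values are non-negative with units (amplitude units)/s; defined at all
    ``t`` through linear interpolation with edge-value extension.
    """

    t: np.ndarray
    rvt: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rvt = np.asarray(self.rvt, dtype=float)
        if not np.all(np.isfinite(self.rvt)):
            raise ValueError("non-finite RVT values")
        if np.any(self.rvt < 0):
            raise ValueError("RVT must be non-negative")

    def at(self, t_eval: np.ndarray) -> np.ndarray:
        """RVT values at arbitrary times (linear interp, edge-hold)."""
        f = interp1d(self.t, self.rvt, kind="linear", bounds_error=False,
                     fill_value=(self.rvt[0], self.rvt[-1]))
        return f(np.asarray(t_eval, dtype=float))


# ---------------------------------------------------------------------------
# small numerical helpers
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of width ``window`` with edge truncation.

    Near the edges the window shrinks to the available samples, so a
    constant input is returned unchanged everywhere.
    """
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median with edge-nearest padding; any window size."""
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    s = pd.Series(x)
    out = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    return out


# ---------------------------------------------------------------------------
# cardiac chain
# ---------------------------------------------------------------------------

def detect_cardiac_peaks(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Detect pulse-wave peaks in a PPG trace.

    Band-limits the signal to the plausible pulse band, then runs an
    adaptive-threshold peak search with a 0.3 s refractory period.

    Parameters
    ----------
    ppg
        Raw PPG samples (>= 5 s of signal).
    fs
        Sampling rate in Hz (>= 50).

    Returns
    -------
    np.ndarray
        Strictly increasing peak times in seconds.
    """
    ppg = np.asarray(ppg, dtype=float)
    if fs < 50:
        raise ValueError("PPG sampling rate must be >= 50 Hz")
    if len(ppg) < 5 * fs:
        raise ValueError("need at least 5 s of PPG signal")
    if np.std(ppg) == 0:
        raise ValueError("no pulsatile component: flat PPG signal")

    # plausible pulse band (30-200 bpm -> 0.5-3.3 Hz fundamental; keep a
    # little headroom for waveform harmonics)
    sos = sps.butter(3, [0.4, 8.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, ppg)

    # adaptive threshold from the amplitude distribution of the filtered trace
    thresh = 0.3 * np.percentile(band, 95)
    distance = max(1, int(round(PPG_REFRACTORY_S * fs)))
    idx, _ = sps.find_peaks(band, height=thresh, distance=distance)
    if len(idx) < 2:
        raise ValueError("no pulsatile component: fewer than two pulse peaks found")
    peaks = idx / fs

    rates = 60.0 / np.diff(peaks)
    if np.any(rates < 30) or np.any(rates > 200):
        logger.warning(
            "implied heart rate outside [30, 200] bpm (range %.1f-%.1f)",
            rates.min(), rates.max(),
        )
    return peaks


def cardiac_phase(peaks: np.ndarray, t_eval: np.ndarray) -> PhaseSeries:
    """Cardiac phase: linear 0 -> 2*pi between successive beats.

    The phase is 0 at each peak and grows linearly to 2*pi at the next
    peak.  Times slightly before the first or after the last peak are
    extrapolated with the nearest inter-beat interval.
    """
    peaks = np.asarray(peaks, dtype=float)
    t_eval = np.asarray(t_eval, dtype=float)
    if len(peaks) < 2:
        raise ValueError("need at least two cardiac peaks")
    span = peaks[-1] - peaks[0]
    if t_eval.min() > peaks[-1] + span or t_eval.max() < peaks[0] - span:
        raise ValueError("evaluation times entirely outside the peak span")

    # index of preceding peak; clip so edges reuse the first/last interval
    prev = np.clip(np.searchsorted(peaks, t_eval, side="right") - 1, 0, len(peaks) - 2)
    ibi = peaks[prev + 1] - peaks[prev]
    frac = (t_eval - peaks[prev]) / ibi
    phase = np.mod(2.0 * np.pi * frac, 2.0 * np.pi)
    return PhaseSeries(t=t_eval, phase=phase, kind="cardiac")


# ---------------------------------------------------------------------------
# respiratory chain
# ---------------------------------------------------------------------------

def _breath_extrema(resp: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of breath peaks and troughs via prominence-guarded search."""
    resp = np.asarray(resp, dtype=float)
    if np.std(resp) == 0:
        raise ValueError("constant respiration trace")
    # breaths are slower than ~1 Hz; demand at least 1 s between extrema
    distance = max(1, int(round(1.0 * fs)))
    prominence = 0.25 * np.std(resp)
    pk, _ = sps.find_peaks(resp, distance=distance, prominence=prominence)
    tr, _ = sps.find_peaks(-resp, distance=distance, prominence=prominence)
    return pk, tr


def respiratory_phase(
    resp: np.ndarray,
    fs: float,
    t_eval: np.ndarray,
    n_bins: int = RESP_PHASE_BINS,
) -> PhaseSeries:
    """Respiratory phase by amplitude-histogram equalization.

    The magnitude of the phase is pi times the empirical CDF of the
    respiration amplitude at the evaluation time; the sign is that of the
    respiration derivative.  A full inhale (maximum amplitude) therefore
    maps to |phase| = pi and the mean amplitude to |phase| ~ pi/2,
    independent of any overall amplitude scaling.
    """
    resp = np.asarray(resp, dtype=float)
    t_eval = np.asarray(t_eval, dtype=float)
    if np.std(resp) == 0:
        raise ValueError("constant respiration trace")

    # lightly smooth before differentiating so the sign is noise-robust
    smooth = moving_average(resp, max(3, int(round(0.2 * fs))))
    drdt = np.gradient(smooth, 1.0 / fs)

    lo, hi = resp.min(), resp.max()
    hist, edges = np.histogram(resp, bins=n_bins, range=(lo, hi))
    cdf = np.cumsum(hist) / hist.sum()

    t_samples = np.arange(len(resp)) / fs
    amp = np.interp(t_eval, t_samples, resp)
    slope = np.interp(t_eval, t_samples, drdt)

    bin_idx = np.clip(np.searchsorted(edges, amp, side="right") - 1, 0, n_bins - 1)
    mag = np.pi * cdf[bin_idx]
    sign = np.where(slope >= 0, 1.0, -1.0)
    phase = sign * mag
    # keep the representable range (-pi, pi]: map -pi to +pi
    phase[phase <= -np.pi] = np.pi
    return PhaseSeries(t=t_eval, phase=phase, kind="respiratory")


def rvt_breath_series(resp: np.ndarray, fs: float) -> RvtSeries:
    """Breath-resolved RVT: (peak - preceding trough) / local period.

    One value per detected breath peak, at the peak time; use
    :meth:`RvtSeries.at` (linear interpolation, edge-value extension) to
    evaluate at arbitrary times.  For a sinusoid of amplitude A and period
    T this equals 2A/T at every breath.
    """
    resp = np.asarray(resp, dtype=float)
    pk, tr = _breath_extrema(resp, fs)
    if len(pk) < 2 or len(tr) < 2:
        raise ValueError("unable to find at least two breath peak/trough pairs")

    t_pk = pk / fs
    rvt_vals = []
    rvt_t = []
    for i, (ip, tp) in enumerate(zip(pk, t_pk)):
        before = tr[tr < ip]
        if len(before) == 0:
            continue
        it = before[-1]
        depth = resp[ip] - resp[it]
        # local period from surrounding peaks (centered difference inside)
        if 0 < i < len(pk) - 1:
            period = (t_pk[i + 1] - t_pk[i - 1]) / 2.0
        elif i == 0 and len(pk) > 1:
            period = t_pk[1] - t_pk[0]
        else:
            period = t_pk[i] - t_pk[i - 1]
        if period <= 0:
            continue
        rvt_vals.append(max(depth, 0.0) / period)
        rvt_t.append(tp)
    if len(rvt_vals) < 2:
        raise ValueError("unable to find at least two breath peak/trough pairs")
    return RvtSeries(t=np.asarray(rvt_t), rvt=np.asarray(rvt_vals))


def compute_rvt(resp: np.ndarray, fs: float, t_eval: np.ndarray) -> RvtSeries:
    """Respiration volume per time at the requested times.

    Breath-resolved values (see :func:`rvt_breath_series`) linearly
    interpolated to ``t_eval`` with edge-value extension.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    series = rvt_breath_series(resp, fs)
    return RvtSeries(t=t_eval, rvt=series.at(t_eval))


# ---------------------------------------------------------------------------
# pupil / skin conductance preprocessing
# ---------------------------------------------------------------------------

def preprocess_pupil(
    raw: PupilRecording,
    smooth_samples: int = PUPIL_SMOOTH_SAMPLES,
    reject_fraction: float = PUPIL_REJECT_FRACTION,
) -> PupilRecording:
    """Clean a pupil trace: interpolate blinks, smooth, apply the rejection rule.

    Invalid runs are replaced by linear interpolation between the nearest
    valid neighbours, the diameter is smoothed with a centered moving
    average over ``smooth_samples`` samples, and the recording is flagged
    ``rejected`` when the raw invalid-sample fraction reaches
    ``reject_fraction`` (>= 10% by default).  The artifact fraction is
    computed on the raw validity flags, before interpolation.
    """
    if not np.any(raw.valid):
        raise ValueError("all pupil samples invalid; nothing to interpolate from")

    frac = raw.artifact_fraction
    pd_ = raw.pd.copy()
    idx = np.arange(len(pd_))
    good = raw.valid
    pd_[~good] = np.interp(idx[~good], idx[good], pd_[good])
    pd_ = moving_average(pd_, smooth_samples)

    rejected = bool(raw.rejected or frac >= reject_fraction)
    if rejected and not raw.rejected:
        logger.warning("pupil recording rejected: artifact fraction %.3f >= %.2f",
                       frac, reject_fraction)
    meta = dict(raw.meta)
    meta["artifact_fraction"] = frac
    return PupilRecording(pd=pd_, valid=np.ones_like(good), fs=raw.fs,
                          trigger_times=raw.trigger_times, t0=raw.t0,
                          rejected=rejected, meta=meta)


def preprocess_sc(
    sc: np.ndarray,
    fs: float,
    median_samples: int = SC_MEDIAN_SAMPLES,
    smooth_samples: int = SC_SMOOTH_SAMPLES,
) -> np.ndarray:
    """Filter a skin-conductance trace: rolling median then moving average.

    Mirrors the acquisition chain (median over 150 samples, smoothing over
    250 samples at 500 Hz).  Output length equals input length.
    """
    sc = np.asarray(sc, dtype=float)
    if len(sc) <= smooth_samples:
        raise ValueError(
            f"skin-conductance trace too short: {len(sc)} <= {smooth_samples} samples")
    out = rolling_median(sc, median_samples)
    out = moving_average(out, smooth_samples)
    return out


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def sync_to_scan(
    rec: PhysioRecording | PupilRecording,
    n_volumes: int,
    tr_s: float,
    n_discard: int = N_DISCARD_VOLUMES,
):
    """Align a recording to scan time, discarding initial dummy volumes.

    Scan time zero is the trigger of the first *retained* volume
    (``n_discard`` volumes dropped from the start).  The recording is
    cropped to the retained-scan window; a recording ending early is
    padded with its edge value and a warning logged.

    Returns a copy of the recording with ``t0`` set and samples restricted
    to [0, (n_volumes - n_discard) * tr_s].
    """
    if len(rec.trigger_times) < 1:
        raise ValueError("at least one scanner trigger is required")
    trig = rec.trigger_times
    if len(trig) >= 2:
        implied = (len(trig) - 1) * np.median(np.diff(trig))
        expected = (n_volumes - 1) * tr_s
        if abs(implied - expected) > tr_s:
            raise ValueError(
                f"trigger train spans {implied:.2f} s but {n_volumes} volumes at "
                f"TR={tr_s} s span {expected:.2f} s (difference > 1 TR)")

    if n_discard >= n_volumes:
        raise ValueError("cannot discard all volumes")
    t_start = trig[n_discard] if len(trig) > n_discard else trig[0] + n_discard * tr_s
    n_keep = n_volumes - n_discard
    duration = n_keep * tr_s

    fs = rec.fs
    i0 = int(round(t_start * fs))
    i1 = i0 + int(round(duration * fs))
    n = rec.n_samples
    if i1 > n:
        logger.warning("recording ends %.2f s before scan end; padding with edge value",
                       (i1 - n) / fs)

    def crop(x: np.ndarray, pad_value=None) -> np.ndarray:
        seg = x[max(i0, 0):min(i1, n)]
        pre = max(0, -i0)
        post = max(0, i1 - n)
        if pre or post:
            pv_l = x[0] if pad_value is None else pad_value
            pv_r = x[-1] if pad_value is None else pad_value
            seg = np.concatenate([np.full(pre, pv_l), seg, np.full(post, pv_r)])
        return seg

    new_triggers = trig[n_discard:] - t_start if len(trig) > n_discard else np.array([0.0])

    if isinstance(rec, PhysioRecording):
        channels = {k: crop(v) for k, v in rec.channels.items()}
        return PhysioRecording(channels=channels, fs=fs, trigger_times=new_triggers,
                               t0=0.0, meta={**rec.meta, "synced": True,
                                             "n_discarded": n_discard})
    elif isinstance(rec, PupilRecording):
        return PupilRecording(pd=crop(rec.pd), valid=crop(rec.valid).astype(bool),
                              fs=fs, trigger_times=new_triggers, t0=0.0,
                              rejected=rec.rejected,
                              meta={**rec.meta, "synced": True, "n_discarded": n_discard})
    raise TypeError(f"unsupported recording type {type(rec)!r}")


# ---------------------------------------------------------------------------
# BIDS-style TSV I/O
# ---------------------------------------------------------------------------

def write_physio_tsv(rec: PhysioRecording, path: str | Path) -> None:
    """Write a physio recording as TSV plus a JSON sidecar (fs, triggers)."""
    path = Path(path)
    df = pd.DataFrame(rec.channels)
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"SamplingFrequency": rec.fs,
               "StartTime": -rec.t0,
               "Columns": list(rec.channels),
               "TriggerTimes": rec.trigger_times.tolist()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_physio_tsv(path: str | Path) -> PhysioRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return PhysioRecording(
        channels={c: df[c].to_numpy() for c in df.columns},
        fs=float(sidecar["SamplingFrequency"]),
        trigger_times=np.asarray(sidecar["TriggerTimes"], dtype=float),
        t0=-float(sidecar.get("StartTime", 0.0)),
    )


def write_pupil_tsv(rec: PupilRecording, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"pd": rec.pd, "valid": rec.valid.astype(int)}).to_csv(
        path, sep="\t", index=False)
    sidecar = {"SamplingFrequency": rec.fs,
               "StartTime": -rec.t0,
               "Rejected": bool(rec.rejected),
               "TriggerTimes": rec.trigger_times.tolist()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_pupil_tsv(path: str | Path) -> PupilRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return PupilRecording(
        pd=df["pd"].to_numpy(), valid=df["valid"].to_numpy().astype(bool),
        fs=float(sidecar["SamplingFrequency"]),
        trigger_times=np.asarray(sidecar["TriggerTimes"], dtype=float),
        t0=-float(sidecar.get("StartTime", 0.0)),
        rejected=bool(sidecar.get("Rejected", False)),
    )
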