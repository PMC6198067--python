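"""Synthetic sessions with known ground truth.

Emulates a brainstem fMRI Stroop session: a 4-D BOLD series contaminated
by cardiac/respiratory phase-locked fluctuations and RVT-coupled drift, a
500 Hz polygraph record (PPG, respiration belt, skin conductance), a
120 Hz pupil trace with blink artifacts, a trial table, and motion
parameters.  Every stochastic element derives from a single seed, so an
identical :class:`GroundTruth` reproduces the session bit-for-bit.

The defaults mirror the study conditions this package targets: 220
volumes at TR = 2.04 s, 18 congruent (CC) + 18 incongruent (IC) stimuli
of 1.5 s at a 10.5 s inter-stimulus interval, incongruent pupil dilations
larger than congruent ones, and skin-conductance responses shaped as a
bi-exponential kernel.  The spatial grid defaults to 20x20x20 voxels so a
full session generates in seconds; timing is untouched by that choice.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONGRUENT, INCONGRUENT, BoldImage, EventDesign
from .physio import PhysioRecording, PupilRecording, cardiac_phase, respiratory_phase

# --- session timing defaults (scanner protocol being emulated) -------------
N_VOLUMES = 220
TR_S = 2.04
N_PER_CONDITION = 18
STIM_DURATION_S = 1.5
ISI_S = 10.5
JITTER_SD_S = 0.5          # onset jitter SD; the protocol jitters onsets but
                           # does not pin down the distribution, so this is a
                           # parameter with a plausible default
PHYSIO_FS_HZ = 500.0
PUPIL_FS_HZ = 120.0
DEFAULT_GRID = (20, 20, 20)

# --- autonomic kernel constants --------------------------------------------
SCR_RISE_TAU_S = 0.75      # skin-conductance response rise time constant
SCR_DECAY_TAU_S = 2.0      # decay time constant
SCR_LATENCY_S = 1.5        # onset latency from stimulus
PUPIL_IRF_N = 10.1         # pupil impulse response shape exponent
PUPIL_IRF_TMAX_S = 0.93    # pupil impulse response time-to-peak
BLINK_DURATION_S = 0.2
PD_BASELINE = 4.0          # resting pupil diameter, a.u. (analysis is ratio-based)
SC_TONIC_US = 5.0          # tonic skin conductance level, microsiemens
BOLD_BASELINE = 1000.0

#: lags (s) of the delayed RVT terms coupled into the BOLD drift
RVT_LAGS_S = (0.0, 5.0, 10.0, 15.0, 20.0)

# per-unit-noise_sd channel noise scales (noise_sd = 0 gives clean physio)
_PPG_NOISE_PER_UNIT = 0.002
_RESP_NOISE_PER_UNIT = 0.002
_SC_NOISE_PER_UNIT = 0.0005
_PD_NOISE_PER_UNIT = 0.002


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic session.

    Amplitude units: BOLD contamination gains and activation betas are in
    raw signal units on a baseline of 1000 (so beta = 10 is a 1% signal
    change); pupil amplitudes are fractions of baseline diameter; SCR
    amplitudes are microsiemens.
    """

    seed: int = 0
    hr_bpm: float = 65.0            # mean heart rate
    hr_sd: float = 0.03             # beat-interval jitter SD (s)
    resp_rate: float = 15.0         # breaths per minute
    resp_amp_mod: float = 0.2       # relative breath-amplitude modulation [0, 1)
    cardiac_gain: float = 8.0       # cardiac phase-locked BOLD contamination
    resp_gain: float = 8.0          # respiratory phase-locked contamination
    rvt_gain: float = 4.0           # lagged-RVT drift coupling
    beta_cc: float = 10.0           # true congruent activation amplitude
    beta_ic: float = 20.0           # true incongruent activation amplitude
    pupil_amp_cc: float = 0.135     # congruent dilation, fraction of baseline
    pupil_amp_ic: float = 0.159     # incongruent dilation
    scr_amp_cc: float = 0.3         # congruent SCR amplitude (uS)
    scr_amp_ic: float = 0.4         # incongruent SCR amplitude (uS)
    blink_rate: float = 10.0        # blinks per minute
    noise_sd: float = 15.0          # BOLD thermal noise SD
    active_voxel_set: tuple = ((10, 10, 10), (10, 11, 10), (11, 10, 10),
                               (10, 10, 11), (9, 10, 10))

    def __post_init__(self) -> None:
        for name in ("hr_bpm", "hr_sd", "resp_rate", "cardiac_gain", "resp_gain",
                     "rvt_gain", "pupil_amp_cc", "pupil_amp_ic", "scr_amp_cc",
                     "scr_amp_ic", "blink_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.resp_amp_mod < 1:
            raise ValueError("resp_amp_mod must lie in [0, 1)")

    @classmethod
    def for_grid(cls, grid: tuple[int, int, int], seed: int = 0,
                 **overrides) -> "GroundTruth":
        """Ground truth with the active blob centred in an arbitrary grid."""
        cx, cy, cz = (g // 2 for g in grid)
        active = ((cx, cy, cz), (cx, cy + 1, cz), (cx + 1, cy, cz),
                  (cx, cy, cz + 1), (cx - 1, cy, cz))
        active = tuple(v for v in active
                       if all(0 <= i < g for i, g in zip(v, grid)))
        overrides.setdefault("active_voxel_set", active)
        return cls(seed=seed, **overrides)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for sub-stream ``stream``."""
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["active_voxel_set"] = [list(v) for v in self.active_voxel_set]
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["active_voxel_set"] = tuple(tuple(v) for v in d["active_voxel_set"])
        return cls(**d)


@dataclass
class SyntheticSession:
    """One complete synthetic session and the truth that generated it."""

    bold: BoldImage
    physio: PhysioRecording
    pupil: PupilRecording
    events: EventDesign
    motion: pd.DataFrame
    truth: GroundTruth

    def __post_init__(self) -> None:
        scan_len = self.bold.n_volumes * self.bold.tr_s
        if self.physio.duration < scan_len:
            raise ValueError("physio recording does not cover the scan")
        if len(self.physio.trigger_times) != self.bold.n_volumes:
            raise ValueError("trigger count does not match volume count")


# ---------------------------------------------------------------------------
# event design
# ---------------------------------------------------------------------------

def gen_event_design(
    n_per_condition: int = N_PER_CONDITION,
    stim_duration_s: float = STIM_DURATION_S,
    isi_s: float = ISI_S,
    jitter_sd_s: float = JITTER_SD_S,
    seed: int = 0,
    start_s: float = 12.0,
    session_duration_s: float | None = None,
    rt_mean_cc_s: float = 1.036,
    rt_sd_cc_s: float = 0.216,
    rt_mean_ic_s: float = 1.223,
    rt_sd_ic_s: float = 0.328,
) -> EventDesign:
    """Generate a pseudorandomized two-condition trial sequence.

    Onsets follow a fixed stimulus-plus-ISI grid with zero-mean Gaussian
    jitter (truncated so onsets stay strictly increasing); conditions are a
    seeded permutation constrained to runs of at most four; reaction times
    are drawn per condition with the incongruent mean above the congruent
    mean.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if stim_duration_s <= 0 or isi_s <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng([int(seed), 11])

    n = 2 * n_per_condition
    spacing = stim_duration_s + isi_s
    # the last trial needs its stimulus plus a 10 s response window, not a
    # full trailing ISI
    required = start_s + (n - 1) * spacing + stim_duration_s + 10.0
    if session_duration_s is not None and required > session_duration_s:
        raise ValueError(
            f"design needs {required:.1f} s but the session lasts only "
            f"{session_duration_s:.1f} s")

    # pseudorandomization: permute until no condition run exceeds 4
    labels = np.array([CONGRUENT] * n_per_condition + [INCONGRUENT] * n_per_condition)
    for _ in range(1000):
        order = rng.permutation(labels)
        runs = np.diff(np.flatnonzero(np.concatenate(
            ([True], order[1:] != order[:-1], [True]))))
        if runs.max() <= 4:
            break
    labels = order

    base = start_s + np.arange(n) * spacing
    if jitter_sd_s > 0:
        cap = min(3.0 * jitter_sd_s, 0.45 * isi_s)
        jitter = np.clip(rng.normal(0.0, jitter_sd_s, n), -cap, cap)
    else:
        jitter = np.zeros(n)
    onsets = base + jitter

    rts = np.where(labels == CONGRUENT,
                   rng.normal(rt_mean_cc_s, rt_sd_cc_s, n),
                   rng.normal(rt_mean_ic_s, rt_sd_ic_s, n))
    rts = np.clip(rts, 0.2, None)

    table = pd.DataFrame({
        "onset": onsets,
        "duration": np.full(n, stim_duration_s),
        "trial_type": labels,
        "response_time": rts,
    })
    return EventDesign(table)


# ---------------------------------------------------------------------------
# autonomic kernels
# ---------------------------------------------------------------------------

def scr_kernel(t: np.ndarray,
               rise_tau: float = SCR_RISE_TAU_S,
               decay_tau: float = SCR_DECAY_TAU_S) -> np.ndarray:
    """Bi-exponential SCR shape, zero for t < 0, normalized to peak 1."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return out / peak


def scr_kernel_peak_time(rise_tau: float = SCR_RISE_TAU_S,
                         decay_tau: float = SCR_DECAY_TAU_S) -> float:
    """Analytic time-to-peak of the bi-exponential kernel (s, post-latency)."""
    return rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)


def pupil_kernel(t: np.ndarray,
                 n: float = PUPIL_IRF_N,
                 t_max: float = PUPIL_IRF_TMAX_S) -> np.ndarray:
    """Gamma-shaped pupillary impulse response, peak 1 at ``t_max`` (~1 s)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        h = np.where(t > 0, (t / t_max) ** n * np.exp(n * (1 - t / t_max)), 0.0)
    return h


# ---------------------------------------------------------------------------
# peripheral recordings
# ---------------------------------------------------------------------------

def gen_physio(
    truth: GroundTruth,
    duration_s: float,
    fs_hz: float = PHYSIO_FS_HZ,
    events: EventDesign | None = None,
    trigger_times: np.ndarray | None = None,
) -> PhysioRecording:
    """Generate PPG, respiration and skin-conductance channels.

    Hidden ground truth for oracle tests is stored in ``meta``: exact beat
    times (``beat_times``), breath peak/trough times, and per-trial SCR
    amplitudes.  The SC channel is a tonic level plus, when ``events`` is
    given, a sum over trials of the bi-exponential SCR kernel scaled by the
    condition amplitude.
    """
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = truth.rng(21)
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz

    # --- PPG: pulse bumps at (possibly jittered) beat times ---
    mean_ibi = 60.0 / truth.hr_bpm
    n_beats = int(np.ceil(duration_s / mean_ibi)) + 2
    ibis = mean_ibi + (rng.normal(0.0, truth.hr_sd, n_beats) if truth.hr_sd > 0
                       else np.zeros(n_beats))
    ibis = np.clip(ibis, 0.3, 2.0)
    beat_times = np.concatenate([[0.0], np.cumsum(ibis)])
    beat_times = beat_times[beat_times <= duration_s + mean_ibi]
    ppg = np.zeros_like(t)
    width = 0.05
    for bt in beat_times:
        lo = np.searchsorted(t, bt - 4 * width)
        hi = np.searchsorted(t, bt + 4 * width)
        ppg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / width) ** 2)
    ppg += truth.noise_sd * _PPG_NOISE_PER_UNIT * rng.standard_normal(len(t))

    # --- respiration: sinusoid with slow amplitude modulation ---
    f_resp = truth.resp_rate / 60.0
    if truth.resp_amp_mod > 0:
        # smooth modulation from low-pass filtered noise, normalized to [-1, 1]
        slow = rng.standard_normal(len(t))
        win = int(round(10.0 * fs_hz))
        kernel = np.hanning(win)
        kernel /= kernel.sum()
        slow = np.convolve(slow, kernel, mode="same")
        denom = np.max(np.abs(slow))
        slow = slow / denom if denom > 0 else slow
        envelope = 1.0 + truth.resp_amp_mod * slow
    else:
        envelope = np.ones_like(t)
    resp = envelope * np.sin(2 * np.pi * f_resp * t)
    resp += truth.noise_sd * _RESP_NOISE_PER_UNIT * rng.standard_normal(len(t))

    period = 1.0 / f_resp
    n_cycles = int(duration_s / period)
    breath_peaks = period / 4 + np.arange(n_cycles) * period
    breath_troughs = 3 * period / 4 + np.arange(n_cycles) * period

    # --- skin conductance: tonic level + slow drift + event-locked SCRs ---
    sc = np.full_like(t, SC_TONIC_US)
    drift = np.cumsum(rng.normal(0.0, 1.0, len(t)))
    drift -= np.linspace(drift[0], drift[-1], len(t))
    mx = np.max(np.abs(drift))
    sc += 0.2 * drift / mx if mx > 0 else 0.0
    trial_scr_amps = None
    if events is not None:
        amps = np.where(events.conditions == INCONGRUENT,
                        truth.scr_amp_ic, truth.scr_amp_cc)
        trial_scr_amps = amps.tolist()
        for onset, amp in zip(events.onsets, amps):
            t0 = onset + SCR_LATENCY_S
            lo = np.searchsorted(t, t0)
            hi = np.searchsorted(t, t0 + 15.0)
            sc[lo:hi] += amp * scr_kernel(t[lo:hi] - t0)
    sc += truth.noise_sd * _SC_NOISE_PER_UNIT * rng.standard_normal(len(t))

    if trigger_times is None:
        trigger_times = np.array([0.0])
    meta = {
        "beat_times": beat_times,
        "breath_peak_times": breath_peaks,
        "breath_trough_times": breath_troughs,
        "trial_scr_amplitudes": trial_scr_amps,
    }
    return PhysioRecording(channels={"ppg": ppg, "respiration": resp, "sc": sc},
                           fs=fs_hz, trigger_times=np.asarray(trigger_times, float),
                           meta=meta)


def gen_pupil(
    truth: GroundTruth,
    events: EventDesign,
    duration_s: float,
    fs_hz: float = PUPIL_FS_HZ,
    trigger_times: np.ndarray | None = None,
) -> PupilRecording:
    """Generate a pupil-diameter trace with event-locked dilations and blinks.

    Dilations use the gamma-shaped pupillary impulse response peaking near
    1 s, scaled per trial by the condition amplitude (fraction of
    baseline).  Blinks arrive as a seeded Poisson process; their samples
    are flagged invalid.  Per-trial true amplitudes are kept in ``meta``.
    """
    if events.onsets[-1] + 10.0 > duration_s:
        raise ValueError("events do not fit within the requested pupil recording")
    rng = truth.rng(31)
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz

    amps = np.where(events.conditions == INCONGRUENT,
                    truth.pupil_amp_ic, truth.pupil_amp_cc).astype(float)
    response = np.zeros_like(t)
    for onset, amp in zip(events.onsets, amps):
        lo = np.searchsorted(t, onset)
        hi = np.searchsorted(t, onset + 8.0)
        response[lo:hi] += amp * pupil_kernel(t[lo:hi] - onset)
    pd_ = PD_BASELINE * (1.0 + response)
    pd_ += truth.noise_sd * _PD_NOISE_PER_UNIT * rng.standard_normal(len(t))

    valid = np.ones(len(t), dtype=bool)
    if truth.blink_rate > 0:
        n_blinks = rng.poisson(truth.blink_rate * duration_s / 60.0)
        starts = rng.uniform(0.0, duration_s - BLINK_DURATION_S, n_blinks)
        for s in starts:
            lo = int(s * fs_hz)
            hi = lo + int(BLINK_DURATION_S * fs_hz)
            valid[lo:hi] = False
            pd_[lo:hi] = 0.0
    frac = float(np.mean(~valid))
    if frac > 0.5:
        raise ValueError(
            f"blink rate renders {frac:.0%} of samples invalid; unusable recording")

    if trigger_times is None:
        trigger_times = np.array([0.0])
    meta = {"trial_amplitudes": amps.tolist(), "invalid_fraction": frac}
    return PupilRecording(pd=pd_, valid=valid, fs=fs_hz,
                          trigger_times=np.asarray(trigger_times, float), meta=meta)


# ---------------------------------------------------------------------------
# BOLD series
# ---------------------------------------------------------------------------

def _hrf_regressors(events: EventDesign, acq_times: np.ndarray) -> dict[str, np.ndarray]:
    """Noise-free neural regressors (HRF * impulse train) at acquisition times."""
    from .glm import condition_regressor  # local import: glm builds on core only
    return {
        cond: condition_regressor(events, cond, acq_times)
        for cond in (CONGRUENT, INCONGRUENT)
    }


def gen_bold(
    truth: GroundTruth,
    events: EventDesign,
    physio: PhysioRecording,
    n_volumes: int = N_VOLUMES,
    tr_s: float = TR_S,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    slice_times: np.ndarray | None = None,
) -> BoldImage:
    """Generate the contaminated BOLD series.

    Each voxel's series is baseline + task response (active voxels only)
    + cardiac and respiratory phase-locked Fourier contamination (orders 1
    and 2, evaluated at the voxel's slice acquisition time) + lagged-RVT
    drift + white thermal noise.  The physiological contamination is
    slice-locked — that is what slice-wise correction models — while the
    task response is sampled at volume onset times for every slice,
    matching data whose slice timing has already been harmonized before
    the GLM.  The per-voxel variance of the injected contamination is
    stored in ``meta["contamination_var"]`` so removal can be quantified
    exactly.
    """
    from .nuisance import rvt_regressors
    from .physio import rvt_breath_series

    n_slices = grid[2]
    if slice_times is None:
        slice_times = np.arange(n_slices) * tr_s / n_slices
    slice_times = np.asarray(slice_times, dtype=float)
    if len(slice_times) != n_slices:
        raise ValueError(f"{len(slice_times)} slice times for {n_slices} slices")
    if physio.duration < n_volumes * tr_s:
        raise ValueError("physio recording shorter than the scan")

    rng = truth.rng(41)
    vol_times = np.arange(n_volumes) * tr_s
    data = np.empty(grid + (n_volumes,), dtype=float)
    contamination_var = np.zeros(grid)

    beat_times = physio.meta["beat_times"]
    resp = physio.channels["respiration"]
    rvt = rvt_breath_series(resp, physio.fs)

    active = {tuple(v): None for v in truth.active_voxel_set}
    for v in active:
        if any(i < 0 or i >= g for i, g in zip(v, grid)):
            raise ValueError(f"active voxel {v} outside grid {grid}")

    n_inplane = grid[0] * grid[1]
    neural = _hrf_regressors(events, vol_times)
    for s in range(n_slices):
        acq = vol_times + slice_times[s]
        phi_c = cardiac_phase(beat_times, acq).phase
        phi_r = respiratory_phase(resp, physio.fs, acq).phase
        fourier = np.column_stack([
            np.cos(phi_c), np.sin(phi_c), np.cos(2 * phi_c), np.sin(2 * phi_c),
            np.cos(phi_r), np.sin(phi_r), np.cos(2 * phi_r), np.sin(2 * phi_r),
        ])  # (n_volumes, 8)
        rvt_cols = rvt_regressors(rvt, acq, lags_s=list(RVT_LAGS_S))

        coef_c = rng.standard_normal((n_inplane, 4)) * truth.cardiac_gain
        coef_r = rng.standard_normal((n_inplane, 4)) * truth.resp_gain
        coef_v = rng.standard_normal((n_inplane, len(RVT_LAGS_S))) * truth.rvt_gain
        contam = (coef_c @ fourier[:, :4].T + coef_r @ fourier[:, 4:].T
                  + coef_v @ rvt_cols.T)  # (n_inplane, n_volumes)

        slab = BOLD_BASELINE + contam
        if truth.noise_sd > 0:
            slab = slab + truth.noise_sd * rng.standard_normal(slab.shape)
        slab = slab.reshape(grid[0], grid[1], n_volumes)
        cvar = contam.var(axis=1, ddof=1).reshape(grid[0], grid[1])

        for (ix, iy, iz) in truth.active_voxel_set:
            if iz == s:
                slab[ix, iy] += (truth.beta_cc * neural[CONGRUENT]
                                 + truth.beta_ic * neural[INCONGRUENT])
        data[:, :, s, :] = slab
        contamination_var[:, :, s] = cvar

    affine = np.diag([1.4, 1.4, 1.4, 1.0])
    return BoldImage(data=data, affine=affine, tr_s=tr_s,
                     slice_times=slice_times, slice_axis=2,
                     meta={"contamination_var": contamination_var,
                           "baseline": BOLD_BASELINE})


# ---------------------------------------------------------------------------
# motion and full-session assembly
# ---------------------------------------------------------------------------

def gen_motion(truth: GroundTruth, n_volumes: int = N_VOLUMES) -> pd.DataFrame:
    """Smooth low-amplitude random-walk motion parameters (6 columns).

    Translations in mm, rotations in radians; nuisance covariates only —
    no motion is applied to the image.
    """
    rng = truth.rng(51)
    cols = {}
    names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    scales = [0.02, 0.02, 0.02, 0.0003, 0.0003, 0.0003]
    for name, scale in zip(names, scales):
        walk = np.cumsum(rng.normal(0.0, scale, n_volumes))
        # light smoothing keeps the walk drift-like rather than jittery
        kernel = np.hanning(9)
        kernel /= kernel.sum()
        cols[name] = np.convolve(walk, kernel, mode="same")
    return pd.DataFrame(cols)


def generate_session(
    truth: GroundTruth,
    n_volumes: int = N_VOLUMES,
    tr_s: float = TR_S,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    n_per_condition: int = N_PER_CONDITION,
    jitter_sd_s: float = JITTER_SD_S,
) -> SyntheticSession:
    """Generate a complete session (BOLD + physiology + pupil + events + motion).

    Event onsets are placed in full-scan time, starting after the window
    that the analysis later discards; the physiology covers the whole scan
    plus a 2 s tail.
    """
    scan_len = n_volumes * tr_s
    triggers = np.arange(n_volumes) * tr_s
    events = gen_event_design(
        n_per_condition=n_per_condition, jitter_sd_s=jitter_sd_s,
        seed=truth.seed, start_s=4 * tr_s + 4.0,
        session_duration_s=scan_len)
    physio = gen_physio(truth, duration_s=scan_len + 2.0, events=events,
                        trigger_times=triggers)
    pupil = gen_pupil(truth, events, duration_s=scan_len + 2.0,
                      trigger_times=triggers)
    bold = gen_bold(truth, events, physio, n_volumes=n_volumes, tr_s=tr_s,
                    grid=grid)
    motion = gen_motion(truth, n_volumes=n_volumes)
    return SyntheticSession(bold=bold, physio=physio, pupil=pupil,
                            events=events, motion=motion, truth=truth)


def write_session(session: SyntheticSession, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a session to disk (NIfTI + TSV/JSON), returning the paths."""
    from .physio import write_physio_tsv, write_pupil_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": out / "bold.nii",
        "physio": out / "physio.tsv",
        "pupil": out / "pupil.tsv",
        "events": out / "events.tsv",
        "motion": out / "motion.tsv",
        "truth": out / "truth.json",
    }
    session.bold.save(paths["bold"])
    write_physio_tsv(session.physio, paths["physio"])
    write_pupil_tsv(session.pupil, paths["pupil"])
    session.events.write_tsv(paths["events"])
    session.motion.to_csv(paths["motion"], sep="\t", index=False)
    session.truth.to_json(paths["truth"])
    np.savetxt(out / "slice_times.txt", session.bold.slice_times)
    return paths
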