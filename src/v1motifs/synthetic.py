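"""Synthetic V1 calcium-imaging recordings with known ground truth.

Emulates the recording regime the downstream analysis assumes: a local
population of L2/3-like excitatory neurons (tens to a few hundred) imaged at
25-33 Hz while full-field drifting gratings are shown in blocks of 12
directions x 3 repetitions (5 s grating, 3 s grey), with the pseudo-random
direction order drawn once and repeated in every block.  Neurons are a mix of
tuned and untuned cells, coupled by a distance-dependent directed ground-truth
weight matrix with small integer synaptic lags, share a running-like
population latent, spike as inhomogeneous Poisson processes, and are read out
through a slow calcium-indicator kernel plus additive measurement noise.

Every quantity the analysis later tries to recover (tuning preference,
directed coupling and its lag, the shared latent) is stored in
:class:`GroundTruth`, so each pipeline stage can be tested against the
generative truth instead of real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import h5py
import numpy as np
from scipy.signal import lfilter

__all__ = [
    "Trial",
    "StimulusSchedule",
    "GroundTruth",
    "Recording",
    "SimConfig",
    "make_schedule",
    "simulate_population",
    "asymmetric_circular_gaussian",
    "save_recording",
    "load_recording",
]

GRATING = "grating"
GREY = "grey"


@dataclass(frozen=True)
class Trial:
    block: int
    kind: str  # "grating" | "grey"
    direction_deg: Optional[float]  # None for grey
    onset_frame: int
    offset_frame: int  # exclusive


@dataclass
class StimulusSchedule:
    """Frame-indexed trial structure of a blocked drifting-grating experiment."""

    frame_rate_hz: float
    trials: list[Trial]
    n_directions: int
    reps_per_block: int
    n_blocks: int
    grating_dur_s: float
    grey_dur_s: float

    @property
    def n_frames(self) -> int:
        return self.trials[-1].offset_frame

    @property
    def frames_per_block(self) -> int:
        return self.n_frames // self.n_blocks

    @property
    def directions(self) -> np.ndarray:
        """The distinct grating directions, ascending, in degrees."""
        ds = sorted({t.direction_deg for t in self.trials if t.kind == GRATING})
        return np.asarray(ds, dtype=float)

    def grating_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.kind == GRATING]

    def grey_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.kind == GREY]

    def block_slices(self) -> list[slice]:
        f = self.frames_per_block
        return [slice(b * f, (b + 1) * f) for b in range(self.n_blocks)]

    def frame_directions(self) -> np.ndarray:
        """Per-frame grating direction in degrees; NaN during grey screens."""
        out = np.full(self.n_frames, np.nan)
        for t in self.trials:
            if t.kind == GRATING:
                out[t.onset_frame : t.offset_frame] = t.direction_deg
        return out

    def frame_mask(self, condition: str) -> np.ndarray:
        """Boolean frame mask for ``"all"``, ``"grating_only"`` or ``"grey_only"``."""
        if condition == "all":
            return np.ones(self.n_frames, dtype=bool)
        if condition not in ("grating_only", "grey_only"):
            raise ValueError(f"unknown frame filter {condition!r}")
        want = GRATING if condition == "grating_only" else GREY
        mask = np.zeros(self.n_frames, dtype=bool)
        for t in self.trials:
            if t.kind == want:
                mask[t.onset_frame : t.offset_frame] = True
        return mask

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trials"] = [asdict(t) for t in self.trials]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        trials = [Trial(**t) for t in d["trials"]]
        kw = {k: v for k, v in d.items() if k != "trials"}
        return cls(trials=trials, **kw)


@dataclass
class GroundTruth:
    positions_um: np.ndarray  # (n, 2)
    is_tuned: np.ndarray  # (n,) bool
    tuning_params: dict  # arrays: baseline_hz, amp1_hz, amp2_hz, sigma_deg, theta_pref_deg
    coupling: np.ndarray  # (n, n) signed, coupling[j, i] = weight of j -> i
    lag_frames: np.ndarray  # (n, n) int, lag of j -> i
    latent_gain: np.ndarray  # (T,) >= 0 shared (running-linked) modulation
    spikes: np.ndarray  # (n, T) counts
    latent_factors: Optional[np.ndarray] = None  # (K, T) extra shared factors
    factor_loadings: Optional[np.ndarray] = None  # (n, K) non-negative


@dataclass
class Recording:
    raw_f: np.ndarray  # (n, T) non-negative fluorescence
    frame_rate_hz: float
    positions_um: np.ndarray
    speed_cm_s: np.ndarray  # (T,)
    schedule: StimulusSchedule
    ground_truth: Optional[GroundTruth] = None

    @property
    def n_neurons(self) -> int:
        return self.raw_f.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw_f.shape[1]


def make_schedule(
    n_blocks: int,
    n_directions: int = 12,
    reps_per_block: int = 3,
    grating_dur_s: float = 5.0,
    grey_dur_s: float = 3.0,
    frame_rate_hz: float = 30.0,
    seed: int = 0,
) -> StimulusSchedule:
    """Build a blocked grating schedule with a single pseudo-random order.

    Each block contains ``reps_per_block`` presentations of each of
    ``n_directions`` evenly spaced directions, shuffled once from ``seed``;
    the same order is reused in every block.  Every grating is preceded by a
    mean-luminance grey trial of ``grey_dur_s``.
    """
    if min(n_blocks, n_directions, reps_per_block) < 1:
        raise ValueError("counts must be >= 1")
    if grating_dur_s <= 0 or grey_dur_s <= 0 or frame_rate_hz <= 0:
        raise ValueError("durations and frame rate must be positive")

    grating_frames = int(np.floor(grating_dur_s * frame_rate_hz))
    grey_frames = int(np.floor(grey_dur_s * frame_rate_hz))
    if grating_frames < 1 or grey_frames < 1:
        raise ValueError("trial duration shorter than one frame")

    directions = np.arange(n_directions) * (360.0 / n_directions)
    order = np.repeat(directions, reps_per_block)
    np.random.default_rng(seed).shuffle(order)  # drawn once, reused per block

    trials: list[Trial] = []
    frame = 0
    for b in range(n_blocks):
        for d in order:
            trials.append(Trial(b, GREY, None, frame, frame + grey_frames))
            frame += grey_frames
            trials.append(Trial(b, GRATING, float(d), frame, frame + grating_frames))
            frame += grating_frames
    return StimulusSchedule(
        frame_rate_hz=frame_rate_hz,
        trials=trials,
        n_directions=n_directions,
        reps_per_block=reps_per_block,
        n_blocks=n_blocks,
        grating_dur_s=grating_dur_s,
        grey_dur_s=grey_dur_s,
    )


def wrap_angle_deg(a):
    """Wrap angles to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    return -(np.mod(-a + 180.0, 360.0) - 180.0)


def asymmetric_circular_gaussian(theta_deg, baseline, amp1, amp2, sigma_deg, theta_pref_deg):
    """Double-peaked circular Gaussian tuning curve.

    ``R(t) = B + A1 exp(-wrap(t - tp)^2 / 2 s^2) + A2 exp(-wrap(t - tp - 180)^2 / 2 s^2)``
    with angular differences wrapped to (-180, 180].
    """
    d1 = wrap_angle_deg(np.asarray(theta_deg) - theta_pref_deg)
    d2 = wrap_angle_deg(np.asarray(theta_deg) - theta_pref_deg - 180.0)
    s2 = 2.0 * sigma_deg**2
    return baseline + amp1 * np.exp(-(d1**2) / s2) + amp2 * np.exp(-(d2**2) / s2)


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    out = np.full_like(y, -50.0)
    pos = y > 1e-12
    out[pos] = np.log(np.expm1(y[pos]))
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the awake mouse V1 regime.

    Rates/amplitudes are in Hz (pre-softplus drive units), geometry in
    micrometres, calcium kernel times in seconds.  ``coupling[j, i]`` adds
    ``weight * spikes_j(t - lag)`` Hz to neuron *i*'s drive.
    """

    n_neurons: int = 150
    tuned_fraction: float = 0.55
    field_diameter_um: float = 800.0
    # distance-dependent coupling kernel: P(j -> i) = base_prob * exp(-d / length)
    conn_base_prob: float = 0.2
    conn_length_um: float = 150.0
    weight_scale: float = 1.0  # multiplies lognormal weights (Hz per presyn spike)
    weight_sigma: float = 0.5  # lognormal sd of weights
    frac_negative: float = 0.1  # fraction of suppressive couplings
    lag_min: int = 1  # ground-truth synaptic lags, frames
    lag_max: int = 3
    baseline_rate_hz: tuple = (0.5, 2.5)
    tuning_amp_hz: tuple = (3.0, 8.0)
    tuning_sigma_deg: tuple = (20.0, 40.0)
    a2_ratio: tuple = (0.0, 0.6)  # opposite-direction amplitude as fraction of amp1
    latent_strength: float = 2.0  # Hz drive of the running-linked latent at level 1
    latent_tau_s: float = 2.0  # OU time constant of the running-like latent
    run_threshold: float = 1.28  # latent level above which the animal "runs"
    # additional slow co-fluctuation factors with heterogeneous non-negative
    # loadings; shared variability in V1 populations is neither rank-1 nor
    # spatially uniform, so each factor is anchored at a random location in
    # the field and its loadings decay with distance (factor_length_um=None
    # makes loadings spatially unstructured instead)
    n_latent_factors: int = 20
    latent_factor_strength: float = 3.0  # Hz scale of factor loadings
    latent_factor_tau_s: float = 1.0
    factor_length_um: Optional[float] = 150.0
    tau_rise_s: float = 0.1  # GCaMP6s-class indicator kernel
    tau_decay_s: float = 1.5
    spike_amp: tuple = (0.15, 0.3)  # dF/F per spike
    noise_sd: float = 0.03  # measurement noise, fraction of F0
    f0_range: tuple = (50.0, 200.0)  # baseline fluorescence, arbitrary units

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SimConfig":
        d = json.loads(s)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


def _calcium_kernel_filter(spikes: np.ndarray, fs: float, tau_r: float, tau_d: float) -> np.ndarray:
    """Convolve spike counts with a normalized difference-of-exponentials kernel."""
    a_d = np.exp(-1.0 / (tau_d * fs))
    a_r = np.exp(-1.0 / (tau_r * fs))
    c = lfilter([1.0], [1.0, -a_d], spikes, axis=-1) - lfilter([1.0], [1.0, -a_r], spikes, axis=-1)
    # normalize so a single spike peaks at 1
    t = np.arange(1, int(10 * tau_d * fs))
    k = a_d**t - a_r**t
    peak = k.max()
    return c / peak


def simulate_population(
    config: SimConfig, schedule: StimulusSchedule, seed: int = 0
) -> tuple[GroundTruth, Recording]:
    """Simulate a coupled, tuned population and its fluorescence recording.

    The generative chain is: per-frame drive (baseline + stimulus tuning +
    lagged recurrent coupling on past spikes + shared latent) -> softplus ->
    Poisson spikes -> indicator-kernel convolution -> ``F0 * (1 + dF/F)`` plus
    Gaussian measurement noise.  Running speed is derived from the same latent
    so that high population activity co-occurs with running.
    """
    if config.tau_rise_s <= 0 or config.tau_decay_s <= 0:
        raise ValueError("calcium kernel time constants must be positive")
    if config.lag_min < 0 or config.lag_max < config.lag_min:
        raise ValueError("invalid lag range")

    rng = np.random.default_rng(seed)
    n = config.n_neurons
    fs = schedule.frame_rate_hz
    T = schedule.n_frames

    # --- geometry: uniform in a disc of the configured field diameter
    r = config.field_diameter_um / 2.0 * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2 * np.pi
    positions = np.column_stack([r * np.cos(phi), r * np.sin(phi)])

    # --- tuning
    is_tuned = np.zeros(n, dtype=bool)
    is_tuned[: int(round(config.tuned_fraction * n))] = True
    rng.shuffle(is_tuned)
    theta_pref = rng.random(n) * 360.0
    sigma = rng.uniform(*config.tuning_sigma_deg, size=n)
    amp1 = rng.uniform(*config.tuning_amp_hz, size=n)
    amp2 = amp1 * rng.uniform(*config.a2_ratio, size=n)
    amp1[~is_tuned] = 0.0
    amp2[~is_tuned] = 0.0
    base_rate = rng.uniform(*config.baseline_rate_hz, size=n)
    tuning_params = {
        "baseline_hz": base_rate,
        "amp1_hz": amp1,
        "amp2_hz": amp2,
        "sigma_deg": sigma,
        "theta_pref_deg": theta_pref,
    }

    # --- distance-dependent directed coupling with integer lags
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    p_conn = config.conn_base_prob * np.exp(-d / config.conn_length_um)
    np.fill_diagonal(p_conn, 0.0)
    connected = rng.random((n, n)) < p_conn
    w = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=(n, n)) * config.weight_scale
    sign = np.where(rng.random((n, n)) < config.frac_negative, -1.0, 1.0)
    coupling = np.where(connected, w * sign, 0.0)
    np.fill_diagonal(coupling, 0.0)
    lag = rng.integers(config.lag_min, config.lag_max + 1, size=(n, n))
    lag[coupling == 0] = 0

    # --- shared running-like latent: rectified OU
    alpha = np.exp(-1.0 / (config.latent_tau_s * fs))
    innov = rng.standard_normal(T) * np.sqrt(1 - alpha**2)
    x = lfilter([1.0], [1.0, -alpha], innov)
    latent = np.maximum(x, 0.0)
    g_i = rng.uniform(0.5, 1.5, size=n) * config.latent_strength

    speed = np.maximum(x - config.run_threshold, 0.0) * 20.0
    speed = speed + np.abs(rng.standard_normal(T)) * 0.02  # encoder jitter, cm/s

    # extra zero-mean slow factors with heterogeneous non-negative loadings
    K = config.n_latent_factors
    factor_drive = np.zeros((n, 1))
    factors = np.zeros((K, T))
    loadings = np.zeros((n, K))
    if K > 0 and config.latent_factor_strength > 0:
        af = np.exp(-1.0 / (config.latent_factor_tau_s * fs))
        innov_f = rng.standard_normal((K, T)) * np.sqrt(1 - af**2)
        factors = lfilter([1.0], [1.0, -af], innov_f, axis=1)
        loadings = np.abs(rng.standard_normal((n, K))) * config.latent_factor_strength
        if config.factor_length_um is not None:
            # anchor each factor in the field; neurons load on nearby factors
            rr = config.field_diameter_um / 2.0 * np.sqrt(rng.random(K))
            aa = rng.random(K) * 2 * np.pi
            centers = np.column_stack([rr * np.cos(aa), rr * np.sin(aa)])
            dist = np.linalg.norm(positions[:, None, :] - centers[None, :, :], axis=-1)
            loadings = loadings * np.exp(-dist / config.factor_length_um)

    # --- per-frame stimulus drive (precomputed)
    frame_dir = schedule.frame_directions()
    dir_grid = schedule.directions
    drive_by_dir = np.zeros((n, len(dir_grid)))
    for k, th in enumerate(dir_grid):
        drive_by_dir[:, k] = asymmetric_circular_gaussian(th, 0.0, amp1, amp2, sigma, theta_pref)
    dir_index = np.full(T, -1, dtype=int)
    grating_frames = ~np.isnan(frame_dir)
    dir_index[grating_frames] = np.searchsorted(dir_grid, frame_dir[grating_frames])
    stim_drive = np.zeros((n, T))
    stim_drive[:, grating_frames] = drive_by_dir[:, dir_index[grating_frames]]

    # --- recurrent Poisson dynamics (strictly causal in lagged spikes)
    base_drive = _inv_softplus(base_rate)
    ext_drive = stim_drive
    ext_drive += base_drive[:, None]
    ext_drive += g_i[:, None] * latent[None, :]
    if K > 0 and config.latent_factor_strength > 0:
        ext_drive += loadings @ factors
    max_lag = int(lag.max()) if coupling.any() else 0
    spikes = np.zeros((n, T), dtype=np.int16)
    # split coupling by lag so each frame is a few mat-vecs
    lag_levels = sorted({int(v) for v in np.unique(lag[coupling != 0])}) if coupling.any() else []
    C_by_lag = {l: np.where(lag == l, coupling, 0.0) for l in lag_levels}
    dt = 1.0 / fs
    for t in range(T):
        drive = ext_drive[:, t]
        for l in lag_levels:
            if l == 0:
                continue  # instantaneous coupling not part of the causal loop
            if t - l >= 0:
                drive = drive + C_by_lag[l].T @ spikes[:, t - l]

        rate = _softplus(drive)
        spikes[:, t] = rng.poisson(rate * dt)

    # --- indicator readout
    amp = rng.uniform(*config.spike_amp, size=n)[:, None]
    calcium = amp * _calcium_kernel_filter(
        spikes.astype(float), fs, config.tau_rise_s, config.tau_decay_s
    )
    f0 = rng.uniform(*config.f0_range, size=n)[:, None]
    raw_f = f0 * (1.0 + calcium) + f0 * config.noise_sd * rng.standard_normal((n, T))
    raw_f = np.maximum(raw_f, 1e-3)

    gt = GroundTruth(
        positions_um=positions,
        is_tuned=is_tuned,
        tuning_params=tuning_params,
        coupling=coupling,
        lag_frames=lag,
        latent_gain=latent,
        spikes=spikes,
        latent_factors=factors if K > 0 else None,
        factor_loadings=loadings if K > 0 else None,
    )
    rec = Recording(
        raw_f=raw_f,
        frame_rate_hz=fs,
        positions_um=positions,
        speed_cm_s=speed,
        schedule=schedule,
        ground_truth=gt,
    )
    return gt, rec


# ---------------------------------------------------------------------------
# container I/O


def save_recording(rec: Recording, path: str) -> None:
    """Write a recording (and ground truth, if any) to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("raw_f", data=rec.raw_f, compression="gzip", track_times=False)
        f.create_dataset("speed_cm_s", data=rec.speed_cm_s, track_times=False)
        f.create_dataset("positions_um", data=rec.positions_um, track_times=False)
        f.attrs["frame_rate_hz"] = rec.frame_rate_hz
        f.attrs["schedule_json"] = json.dumps(rec.schedule.to_dict())
        if rec.ground_truth is not None:
            g = f.create_group("ground_truth")
            gt = rec.ground_truth
            g.create_dataset("positions_um", data=gt.positions_um, track_times=False)
            g.create_dataset("is_tuned", data=gt.is_tuned, track_times=False)
            g.create_dataset("coupling", data=gt.coupling, track_times=False)
            g.create_dataset("lag_frames", data=gt.lag_frames, track_times=False)
            g.create_dataset("latent_gain", data=gt.latent_gain, track_times=False)
            g.create_dataset("spikes", data=gt.spikes, compression="gzip", track_times=False)
            for k, v in gt.tuning_params.items():
                g.create_dataset(f"tuning/{k}", data=v, track_times=False)


def load_recording(path: str) -> Recording:
    with h5py.File(path, "r") as f:
        schedule = StimulusSchedule.from_dict(json.loads(f.attrs["schedule_json"]))
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruth(
                positions_um=g["positions_um"][...],
                is_tuned=g["is_tuned"][...].astype(bool),
                tuning_params={k: g[f"tuning/{k}"][...] for k in g["tuning"]},
                coupling=g["coupling"][...],
                lag_frames=g["lag_frames"][...],
                latent_gain=g["latent_gain"][...],
                spikes=g["spikes"][...],
            )
        return Recording(
            raw_f=f["raw_f"][...],
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            positions_um=f["positions_um"][...],
            speed_cm_s=f["speed_cm_s"][...],
            schedule=schedule,
            ground_truth=gt,
        )
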