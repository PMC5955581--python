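"""Fluorescence normalization and trial-level response summaries.

The baseline :math:`F_0(t)` is a slow, transient-free version of the raw
trace: frames dominated by spike-induced transients are masked by a running
robust threshold, interpolated, and the result is smoothed with a 4th-order,
81-point Savitzky-Golay filter.  Traces are then expressed as percent change
from this time-varying baseline, ``dF/F0 = 100 * (F - F0) / F0``.

Trial responses follow the windows used for tuning classification: the mean
dF/F over the entire grating presentation, and over only the final portion
(default 1500 ms) of each grey period so that decaying grating transients do
not leak into the grey estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import savgol_filter

from .synthetic import GRATING, GREY, Recording, StimulusSchedule

__all__ = [
    "DffTraces",
    "TrialResponses",
    "estimate_baseline",
    "compute_dff",
    "trial_means",
    "silent_mask",
    "population_summary",
    "running_by_activity",
]


@dataclass
class DffTraces:
    dff: np.ndarray  # (n, T), percent change from baseline
    baseline_f0: np.ndarray  # (n, T), > 0
    frame_rate_hz: float

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class TrialResponses:
    responses: np.ndarray  # (n, n_trials) mean dF/F in each trial window
    trial_meta: pd.DataFrame  # block, kind, direction, onset, offset per trial
    grating_window_ms: float
    grey_window_ms: float

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    def condition(self, kind: str) -> np.ndarray:
        """Responses restricted to grating or grey trials, (n, n_kind_trials)."""
        cols = np.flatnonzero((self.trial_meta["kind"] == kind).to_numpy())
        return self.responses[:, cols]

    def grating_directions(self) -> np.ndarray:
        m = self.trial_meta
        return m.loc[m["kind"] == GRATING, "direction"].to_numpy(dtype=float)


def estimate_baseline(
    raw_trace: np.ndarray,
    sg_order: int = 4,
    sg_window: int = 81,
    transient_sd: float = 3.0,
) -> np.ndarray:
    """Time-varying baseline of one fluorescence trace.

    Frames exceeding a running median by ``transient_sd`` robust standard
    deviations (1.4826 * MAD of the residual around the running median) are
    treated as spike transients, masked and linearly interpolated, and the
    cleaned trace is Savitzky-Golay smoothed.
    """
    x = np.asarray(raw_trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("raw_trace must be 1-D")
    if sg_window % 2 == 0:
        raise ValueError("sg_window must be odd")
    if x.size <= sg_window:
        raise ValueError(f"trace length {x.size} must exceed sg_window {sg_window}")

    # The running robust center must span several transient decay times,
    # otherwise it rides up on the transients it is meant to reject; the
    # Savitzky-Golay window alone (81 frames ~ 2.5-4 s) is shorter than a
    # slow-indicator transient, so the center uses a 4x longer horizon.
    center_window = 4 * sg_window + 1
    center = median_filter(x, size=min(center_window, x.size // 2 * 2 + 1), mode="nearest")
    resid = x - center
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    # with zero MAD (noise-free trace) any positive excursion is a transient
    masked = resid > transient_sd * robust_sd
    if masked.any():
        # indicator transients decay slowly; extend each masked run forward
        # so sub-threshold decay tails do not leak into the baseline
        from scipy.ndimage import binary_dilation

        structure = np.ones(sg_window + 1, dtype=bool)
        origin = -(sg_window // 2)  # dilate forward in time only
        masked = binary_dilation(masked, structure=structure, origin=origin)
    keep = ~masked
    if not keep.all():
        if keep.sum() < 2:  # pathological: everything flagged
            cleaned = center
        else:
            # interpolate across masked runs from a smoothed sequence of the
            # *kept* samples only, so noisy single endpoints do not tilt the
            # bridged segment and masked frames never leak into the anchors
            idx = np.arange(x.size)
            k_smooth = uniform_filter1d(x[keep], size=25, mode="nearest")
            cleaned = x.copy()
            cleaned[~keep] = np.interp(idx[~keep], idx[keep], k_smooth)
    else:
        cleaned = x
    baseline = savgol_filter(cleaned, sg_window, sg_order, mode="interp")
    # fluorescence baselines are physically positive; guard against overshoot
    floor = 1e-6 * max(np.median(np.abs(x)), 1.0)
    return np.maximum(baseline, floor)


def compute_dff(rec: Recording, baseline: np.ndarray) -> DffTraces:
    """Percent change from baseline, ``100 * (raw - F0) / F0``."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != rec.raw_f.shape:
        raise ValueError("baseline shape must match raw fluorescence")
    bad = np.argwhere(baseline <= 0)
    if bad.size:
        i, t = bad[0]
        raise ValueError(f"non-positive baseline at neuron {i}, frame {t}")
    dff = 100.0 * (rec.raw_f - baseline) / baseline
    return DffTraces(dff=dff, baseline_f0=baseline, frame_rate_hz=rec.frame_rate_hz)


def preprocess(rec: Recording, sg_order: int = 4, sg_window: int = 81, transient_sd: float = 3.0) -> DffTraces:
    """Baseline every neuron and return dF/F traces."""
    baseline = np.vstack(
        [estimate_baseline(tr, sg_order, sg_window, transient_sd) for tr in rec.raw_f]
    )
    return compute_dff(rec, baseline)


def trial_means(
    dff: DffTraces,
    schedule: StimulusSchedule,
    grey_window_ms: float = 1500.0,
) -> TrialResponses:
    """Mean dF/F per trial: full grating window, final ``grey_window_ms`` of grey."""
    if schedule.n_frames > dff.n_frames:
        raise ValueError("schedule extends past the recorded frames")
    grey_frames = int(np.floor(grey_window_ms / 1000.0 * dff.frame_rate_hz))
    rows = []
    cols = []
    for t in schedule.trials:
        if t.kind == GREY:
            on = t.offset_frame - grey_frames
            if on < t.onset_frame or grey_frames < 1:
                raise ValueError("grey window empty after frame rounding")
        else:
            on = t.onset_frame
        cols.append(dff.dff[:, on : t.offset_frame].mean(axis=1))
        rows.append((t.block, t.kind, t.direction_deg, t.onset_frame, t.offset_frame))
    meta = pd.DataFrame(rows, columns=["block", "kind", "direction", "onset", "offset"])
    return TrialResponses(
        responses=np.column_stack(cols),
        trial_meta=meta,
        grating_window_ms=schedule.grating_dur_s * 1000.0,
        grey_window_ms=grey_window_ms,
    )


def baseline_noise_sd(dff: DffTraces) -> np.ndarray:
    """Per-neuron SD of the normalized residual trace, in dF/F percent units."""
    return dff.dff.std(axis=1)


def silent_mask(
    dff: DffTraces,
    trial,
    sd_factor: float = 2.0,
    noise_sd: np.ndarray | None = None,
) -> np.ndarray:
    """Flag neurons with no frame above ``sd_factor`` noise SDs within a trial.

    ``noise_sd`` defaults to each neuron's dF/F SD over the full recording.
    """
    if noise_sd is None:
        noise_sd = baseline_noise_sd(dff)
    window = dff.dff[:, trial.onset_frame : trial.offset_frame]
    return ~(window > sd_factor * noise_sd[:, None]).any(axis=1)


def population_summary(
    dff: DffTraces,
    schedule: StimulusSchedule,
    classes: np.ndarray,
    sd_factor: float = 2.0,
    labels=None,
) -> dict:
    """Stimulus-locked population time courses and single-trial distributions.

    For each class label, returns the median and quartiles across neurons of
    per-neuron z-scored dF/F aligned to grating onset (with the preceding and
    following grey periods as flanks), with per-trial silent neurons removed,
    plus the z-scored single-trial response distributions per condition.
    """
    import warnings

    classes = np.asarray(classes)
    fs = dff.frame_rate_hz
    grey_frames = int(np.floor(schedule.grey_dur_s * fs))
    grating_frames = int(np.floor(schedule.grating_dur_s * fs))
    span = grey_frames + grating_frames + grey_frames

    z = (dff.dff - dff.dff.mean(axis=1, keepdims=True)) / dff.dff.std(axis=1, keepdims=True)
    noise_sd = baseline_noise_sd(dff)

    tr = trial_means(dff, schedule)
    grating_cols = np.flatnonzero((tr.trial_meta["kind"] == GRATING).to_numpy())
    grey_cols = np.flatnonzero((tr.trial_meta["kind"] == GREY).to_numpy())
    resp = tr.responses
    zresp = (resp - resp.mean(axis=1, keepdims=True)) / resp.std(axis=1, keepdims=True)

    out: dict = {"time_s": (np.arange(span) - grey_frames) / fs, "classes": {}}
    gratings = schedule.grating_trials()
    if labels is None:
        labels = np.unique(classes)
    for label in labels:
        members = np.flatnonzero(classes == label)
        if members.size == 0:
            warnings.warn(f"class {label!r} has no members; empty summary")
            out["classes"][label] = {}
            continue
        # per-neuron trial-mean time course (silent trials removed per neuron),
        # then quartiles across neurons
        sums = np.zeros((members.size, span))
        counts = np.zeros(members.size)
        for g in gratings:
            lo = g.onset_frame - grey_frames
            hi = g.offset_frame + grey_frames
            if lo < 0 or hi > dff.n_frames:
                continue
            active = ~silent_mask(dff, g, sd_factor, noise_sd)
            sel = active[members]
            sums[sel] += z[members[sel], lo:hi]
            counts[sel] += 1
        has_trials = counts > 0
        per_neuron = sums[has_trials] / counts[has_trials, None]
        q = (
            np.percentile(per_neuron, [25, 50, 75], axis=0)
            if per_neuron.shape[0]
            else np.full((3, span), np.nan)
        )
        out["classes"][label] = {
            "q25": q[0],
            "median": q[1],
            "q75": q[2],
            "grating_zresponses": zresp[np.ix_(members, grating_cols)],
            "grey_zresponses": zresp[np.ix_(members, grey_cols)],
        }
    return out


def running_by_activity(
    dff: DffTraces,
    speed_cm_s: np.ndarray,
    n_quantiles: int = 10,
    speed_threshold: float = 0.1,
) -> np.ndarray:
    """Probability of running per equal-count quantile of total fluorescence."""
    speed = np.asarray(speed_cm_s, dtype=float)
    if speed.size != dff.n_frames:
        raise ValueError("speed trace must align with frames")
    if dff.n_frames < n_quantiles:
        raise ValueError("fewer frames than quantiles")
    total = dff.dff.sum(axis=0)
    order = np.argsort(total, kind="stable")
    bins = np.array_split(order, n_quantiles)
    return np.array([(speed[b] > speed_threshold).mean() for b in bins])
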