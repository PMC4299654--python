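"""Derandomized trial-response extraction.

In a well-designed episodic experiment the stimulus order is randomized
independently in every block, so the interesting structure — one trace
per (cell, stimulus, trial) — is scattered through the recording.  This
module undoes that: ROI traces are averaged from the processed stack,
frames are regrouped by stimulus into presentation-ordered trials
(derandomization), and a pluggable response measure (mean, peak, or
FRET channel ratio over the stimulus use window) condenses each trial
to a number.  The result is a response matrix
``(n_rois, n_stimuli, n_trials)`` plus per-stimulus trial-averaged
PSTH traces.

Scaling: ``raw`` uses black-subtracted trace values; ``dff`` converts
each frame to (F - F0)/F0 against the baseline assignment covering that
frame *before* the measure is applied, so "peak dF/F0" means the peak
of the dF/F0 trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import NoBaselineError, dff as _dff, ratio as _ratio

__all__ = [
    "RegionTraces",
    "TrialMap",
    "ResponseMatrix",
    "extract_region_traces",
    "derandomize",
    "extract_region_responses",
    "psth",
    "save_responses",
]


@dataclass
class RegionTraces:
    """Per-ROI, per-frame, per-channel processed trace values.

    A trace sample is the mean over the ROI's *valid* pixels (pixels made
    NaN by shift borders are excluded); a frame with no valid pixel is NaN.
    """

    values: np.ndarray  # (n_rois, n_frames, n_channels)
    frame_info: pd.DataFrame


@dataclass
class TrialMap:
    """Mapping (stimulus_id, trial, frame_in_trial) -> global frame index.

    ``trials[stim_id]`` lists, in presentation order, one frame-index
    array per trial of that stimulus.  The mapping is injective: a global
    frame appears in at most one trial.
    """

    trials: dict = field(default_factory=dict)  # stim_id -> [np.ndarray, ...]
    presentation_of_trial: dict = field(default_factory=dict)
    # (stim_id, trial) -> 0-based presentation index

    @property
    def stim_ids(self) -> list[int]:
        return sorted(self.trials)

    def n_trials(self, stim_id: int) -> int:
        return len(self.trials.get(stim_id, []))

    def frames(self, stim_id: int, trial: int) -> np.ndarray:
        return self.trials[stim_id][trial]

    def all_mapped_frames(self) -> np.ndarray:
        parts = [f for lst in self.trials.values() for f in lst]
        return np.concatenate(parts) if parts else np.empty(0, dtype=int)


def extract_region_traces(stack, rois, chunk: int = 128) -> RegionTraces:
    """Average processed pixel values within each ROI, frame by frame.

    Runs blockwise over frames so memory stays bounded by one chunk of
    frames regardless of stack length.
    """
    if len(rois) == 0:
        raise ValueError("RoiSet is empty")
    if rois.image_dims != (stack.shape[0], stack.shape[1]):
        raise ValueError(
            f"RoiSet dims {rois.image_dims} do not match stack frame "
            f"dims {(stack.shape[0], stack.shape[1])}"
        )
    n_rois, n_frames, n_ch = len(rois), stack.n_frames, stack.n_channels
    values = np.full((n_rois, n_frames, n_ch), np.nan)
    flat_regions = [reg for reg in rois.regions]
    for ch in range(n_ch):
        for lo in range(0, n_frames, chunk):
            hi = min(lo + chunk, n_frames)
            block = stack.get_frames(np.arange(lo, hi), channel=ch,
                                     processed=True)
            flat = block.reshape(-1, hi - lo)
            for k, reg in enumerate(flat_regions):
                pix = flat[reg, :]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    values[k, lo:hi, ch] = np.nanmean(pix, axis=0)
    return RegionTraces(values, stack.frame_stimulus_info())


def derandomize(frame_info: pd.DataFrame, timeline) -> TrialMap:
    """Regroup frames by stimulus into presentation-ordered trials.

    For each stimulus ID, trials are its presentations in timeline order;
    each trial's frames are the tagged frames of that presentation in
    acquisition order.  Presentations that caught no frames are skipped.
    """
    tm = TrialMap()
    tagged = frame_info[frame_info["presentation_index"].notna()]
    frames_of_pres: dict[int, np.ndarray] = {}
    for pres0, grp in tagged.groupby(
        tagged["presentation_index"].astype(int) - 1
    ):
        frames_of_pres[int(pres0)] = grp["frame"].to_numpy()
    for pres0 in range(timeline.n_presentations):
        if pres0 not in frames_of_pres:
            continue
        sid = int(timeline.presentation_stim_id[pres0])
        lst = tm.trials.setdefault(sid, [])
        tm.presentation_of_trial[(sid, len(lst))] = pres0
        lst.append(np.sort(frames_of_pres[pres0]))
    return tm


@dataclass
class ResponseMatrix:
    """Derandomized per-trial responses and PSTHs.

    ``responses[r, s, t]`` is ROI ``r``'s response to stimulus
    ``stim_ids[s]`` on trial ``t`` (NaN where a stimulus has fewer trials
    or a trial had no usable frames).  ``psth[stim_id]`` is the
    ``(n_rois, n_frames)`` trial-averaged trace, trials truncated to the
    shortest trial of that stimulus.  ``trial_avg`` is the mean over
    non-invalid trials.
    """

    responses: np.ndarray  # (n_rois, n_stimuli, n_trials)
    stim_ids: list
    measure: str
    scale: str
    psth: dict
    trial_avg: np.ndarray  # (n_rois, n_stimuli)
    trial_map: TrialMap


def _roi_baselines(stack, rois, channel: int) -> dict[tuple[int, int], np.ndarray]:
    """Per baseline entry, the ROI-mean F0 for each ROI (NaN-safe)."""
    out = {}
    for entry in stack.baseline:
        if entry.channel != channel:
            continue
        flat = entry.mean_frame.ravel()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.array([np.nanmean(flat[reg]) for reg in rois.regions])
        out[entry.target_range] = vals
    return out


def _frame_f0(stack, rois, channel, frames) -> np.ndarray:
    """(n_rois, n_frames) ROI-mean F0 for each frame; errors if uncovered."""
    per_entry = _roi_baselines(stack, rois, channel)
    entries = [e for e in stack.baseline if e.channel == channel]
    out = np.empty((len(rois), len(frames)))
    for j, f in enumerate(frames):
        for e in entries:
            if e.covers(int(f)):
                out[:, j] = per_entry[e.target_range]
                break
        else:
            raise NoBaselineError(
                f"frame {int(f)} has no baseline assignment on channel {channel}"
            )
    return out


def extract_region_responses(
    stack,
    rois,
    measure: str = "mean",
    scale: str = "raw",
    channel: int = 0,
    ratio_channels: tuple[int, int] = (0, 1),
    traces: RegionTraces | None = None,
) -> ResponseMatrix:
    """Derandomize, segment and measure per-trial ROI responses.

    Per (roi, stimulus, trial): the trace is restricted to the trial's
    frames flagged ``use_frame`` (the stimulus use window), scaled
    (``raw`` or per-frame ``dff``), then condensed by ``measure``:
    ``mean``, ``peak`` (max of the unsmoothed trace), or ``ratio``
    (mean of the channel-a / channel-b trace; FRET readout, applied to
    black-subtracted raw traces).
    """
    if measure not in ("mean", "peak", "ratio"):
        raise ValueError(f"unknown measure {measure!r}")
    if scale not in ("raw", "dff"):
        raise ValueError(f"unknown scale {scale!r}")
    if measure == "ratio" and stack.n_channels < 2:
        raise ValueError("ratio measure requires a 2-channel stack")
    if traces is None:
        traces = extract_region_traces(stack, rois)
    fi = traces.frame_info
    tm = derandomize(fi, stack.timeline)
    stim_ids = tm.stim_ids
    n_rois = traces.values.shape[0]
    n_trials = max((tm.n_trials(s) for s in stim_ids), default=0)
    use_flags = fi.set_index("frame")["use_frame"]

    if scale == "dff" and not stack.baseline:
        raise NoBaselineError("scale='dff' requires a baseline assignment")

    def scaled_trace(frames: np.ndarray) -> np.ndarray:
        """(n_rois, len(frames)) trace on the requested scale."""
        if measure == "ratio":
            ca, cb = ratio_channels
            return _ratio(traces.values[:, frames, ca],
                          traces.values[:, frames, cb])
        tr = traces.values[:, frames, channel]
        if scale == "raw":
            return tr
        f0 = _frame_f0(stack, rois, channel, frames)
        return _dff(tr, f0)

    responses = np.full((n_rois, len(stim_ids), n_trials), np.nan)
    for s_idx, sid in enumerate(stim_ids):
        for t in range(tm.n_trials(sid)):
            frames = tm.frames(sid, t)
            use = frames[use_flags.loc[frames].to_numpy(dtype=bool)]
            if use.size == 0:
                warnings.warn(
                    f"stimulus {sid} trial {t}: no usable frames; "
                    "response marked invalid",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            tr = scaled_trace(use)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if measure == "peak":
                    responses[:, s_idx, t] = np.nanmax(tr, axis=1)
                else:  # mean, ratio (already a per-frame ratio trace)
                    responses[:, s_idx, t] = np.nanmean(tr, axis=1)

    psth_traces = {}
    for sid in stim_ids:
        lengths = [len(tm.frames(sid, t)) for t in range(tm.n_trials(sid))]
        min_len = min(lengths)
        stackv = np.stack(
            [scaled_trace(tm.frames(sid, t)[:min_len])
             for t in range(tm.n_trials(sid))],
            axis=0,
        )  # (n_trials, n_rois, min_len)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            psth_traces[sid] = np.nanmean(stackv, axis=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        trial_avg = np.nanmean(responses, axis=2)
    return ResponseMatrix(
        responses, stim_ids, measure, scale, psth_traces, trial_avg, tm
    )


def psth(matrix: ResponseMatrix) -> dict:
    """Per-stimulus trial-averaged traces (trials truncated to the
    shortest trial of each stimulus before frame-wise averaging)."""
    return matrix.psth


def save_responses(matrix: ResponseMatrix, out_prefix: str) -> None:
    """Write responses as long CSV, PSTHs as CSV, and a JSON summary."""
    import json

    rows = []
    n_rois = matrix.responses.shape[0]
    for r in range(n_rois):
        for s_idx, sid in enumerate(matrix.stim_ids):
            for t in range(matrix.responses.shape[2]):
                v = matrix.responses[r, s_idx, t]
                if np.isfinite(v):
                    rows.append((r, sid, t + 1, matrix.measure, v))
    pd.DataFrame(
        rows, columns=["roi", "stimulus", "trial", "measure", "value"]
    ).to_csv(out_prefix + "_responses.csv", index=False)

    psth_rows = []
    for sid, tr in matrix.psth.items():
        for r in range(tr.shape[0]):
            for f in range(tr.shape[1]):
                psth_rows.append((sid, r, f, tr[r, f]))
    pd.DataFrame(
        psth_rows, columns=["stimulus", "roi", "frame_in_trial", "value"]
    ).to_csv(out_prefix + "_psth.csv", index=False)

    summary = {
        "n_rois": int(n_rois),
        "stim_ids": [int(s) for s in matrix.stim_ids],
        "n_trials": int(matrix.responses.shape[2]),
        "measure": matrix.measure,
        "scale": matrix.scale,
        "trial_avg": np.where(
            np.isfinite(matrix.trial_avg), matrix.trial_avg, None
        ).tolist(),
    }
    with open(out_prefix + "_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
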