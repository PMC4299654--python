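"""Black-level and baseline-fluorescence (F0) machinery.

Photomultiplier offsets mean that a raw pixel value of zero does not
correspond to zero fluorescence.  The *black level* is estimated per
frame as the mean raw value over a user-chosen region expected to have
no fluorescence (classically the interior of a blood vessel) and is
subtracted from every signal before further processing.

The *baseline distribution* is the per-pixel mean and sample standard
deviation of black-subtracted, re-registered frames acquired during
blank (no-stimulus) periods.  Each baseline estimate is attached to a
half-open range of stack frames, so a drifting baseline can be tracked
with a handful of frames of storage.  The differential calcium response
is then dF/F0 = (F - F0) / F0, and for dual-fluorophore (FRET-style)
indicators the response is the ratio of the two channels.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineEntry",
    "BaselineOverlapError",
    "NoBaselineError",
    "define_black_region",
    "assign_blank_frames",
    "get_blank_frames",
    "dff",
    "ratio",
    "save_baseline",
    "load_baseline",
]


class BaselineOverlapError(ValueError):
    """A new baseline entry overlaps an existing one on the same channel."""


class NoBaselineError(LookupError):
    """A frame has no covering baseline assignment."""


@dataclass
class BaselineEntry:
    """Per-pixel baseline distribution for a half-open frame range."""

    target_range: tuple[int, int]  # [start, stop)
    channel: int
    mean_frame: np.ndarray  # per-pixel F0 mean, black-subtracted units
    std_frame: np.ndarray  # per-pixel F0 sample s.d. (ddof=1)

    def covers(self, frame: int) -> bool:
        return self.target_range[0] <= frame < self.target_range[1]


def define_black_region(
    stack, pixel_indices: Sequence[int], channel: int = 0, chunk: int = 256
) -> np.ndarray:
    """Assign the per-frame black level from a zero-fluorescence region.

    ``pixel_indices`` are linear (row-major) indices into the frame grid.
    The black level of each frame is the mean raw value over the region
    in the given channel; the resulting trace is assigned to
    ``stack.black_trace`` and returned.
    """
    idx = np.asarray(pixel_indices, dtype=np.intp).ravel()
    if idx.size == 0:
        raise ValueError("black region must contain at least one pixel")
    nr, nc = stack.shape[0], stack.shape[1]
    if idx.min() < 0 or idx.max() >= nr * nc:
        raise IndexError(
            f"pixel index out of range for {nr} x {nc} frame grid"
        )
    rows, cols = np.unravel_index(idx, (nr, nc))
    n = stack.n_frames
    trace = np.empty(n, dtype=float)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = stack.get_frames(np.arange(lo, hi), channel=channel, processed=False)
        trace[lo:hi] = block[rows, cols, :].astype(float).mean(axis=0)
    stack.set_black_trace(trace)
    return trace


def assign_blank_frames(
    stack,
    source_frames: Sequence[int],
    target_range: tuple[int, int],
    channel: int = 0,
) -> BaselineEntry:
    """Estimate a baseline distribution and attach it to a frame range.

    Per pixel, F0 mean and sample s.d. (ddof=1) over the black-subtracted,
    re-registered source frames.  Requires at least two source frames and
    a target range disjoint from existing entries on the same channel.
    """
    source_frames = np.asarray(source_frames, dtype=int)
    if source_frames.size < 2:
        raise ValueError("need at least 2 source frames (sample s.d. undefined)")
    start, stop = int(target_range[0]), int(target_range[1])
    if not 0 <= start < stop <= stack.n_frames:
        raise ValueError(f"invalid target range [{start}, {stop})")
    for entry in stack.baseline:
        if entry.channel == channel and not (
            stop <= entry.target_range[0] or start >= entry.target_range[1]
        ):
            raise BaselineOverlapError(
                f"range [{start}, {stop}) overlaps existing "
                f"[{entry.target_range[0]}, {entry.target_range[1]}) "
                f"on channel {channel}"
            )
    frames = stack.get_frames(source_frames, channel=channel, processed=True)
    with np.errstate(invalid="ignore"):
        mean_frame = np.nanmean(frames, axis=2)
        std_frame = np.nanstd(frames, axis=2, ddof=1)
    entry = BaselineEntry((start, stop), channel, mean_frame, std_frame)
    stack.baseline.append(entry)
    return entry


def get_blank_frames(
    stack, frame_indices: Sequence[int], channel: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline (F0 mean, F0 s.d.) frames covering each requested frame.

    Returns two ``(n_rows, n_cols, n_frames)`` arrays.  Ranges are
    half-open, so a frame at a range's stop index belongs to the next one.
    """
    frames = np.asarray(frame_indices, dtype=int)
    entries = [e for e in stack.baseline if e.channel == channel]
    nr, nc = stack.shape[0], stack.shape[1]
    means = np.empty((nr, nc, frames.size))
    stds = np.empty((nr, nc, frames.size))
    for k, f in enumerate(frames):
        for entry in entries:
            if entry.covers(int(f)):
                means[:, :, k] = entry.mean_frame
                stds[:, :, k] = entry.std_frame
                break
        else:
            raise NoBaselineError(
                f"frame {int(f)} has no baseline assignment on channel {channel}"
            )
    return means, stds


def dff(f, f0):
    """Differential response (F - F0) / F0 of black-subtracted signals.

    Where F0 <= 0 the result is NaN (logged): a non-positive baseline
    means the pixel carries no usable fluorescence.
    """
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    bad = ~(f0 > 0)
    if np.any(bad):
        logger.warning(
            "dff: %d value(s) with F0 <= 0 marked invalid", int(np.sum(bad))
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (f - f0) / f0
    out = np.where(bad, np.nan, out)
    return float(out) if out.ndim == 0 else out


def ratio(fa, fb):
    """Channel ratio Fa / Fb of black-subtracted signals; Fb <= 0 is NaN."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    bad = ~(fb > 0)
    if np.any(bad):
        logger.warning(
            "ratio: %d value(s) with denominator <= 0 marked invalid",
            int(np.sum(bad)),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = fa / fb
    out = np.where(bad, np.nan, out)
    return float(out) if out.ndim == 0 else out


def save_baseline(stack, directory: str) -> None:
    """Write each baseline entry as an .npz plus a JSON range index."""
    os.makedirs(directory, exist_ok=True)
    index = []
    for k, entry in enumerate(stack.baseline):
        fname = f"baseline_{k:03d}.npz"
        np.savez(
            os.path.join(directory, fname),
            mean=entry.mean_frame,
            std=entry.std_frame,
        )
        index.append(
            {
                "file": fname,
                "start": entry.target_range[0],
                "stop": entry.target_range[1],
                "channel": entry.channel,
            }
        )
    with open(os.path.join(directory, "baseline_index.json"), "w") as fh:
        json.dump(index, fh, indent=1)


def load_baseline(stack, directory: str) -> None:
    with open(os.path.join(directory, "baseline_index.json")) as fh:
        index = json.load(fh)
    stack.baseline = []
    for rec in index:
        data = np.load(os.path.join(directory, rec["file"]))
        stack.baseline.append(
            BaselineEntry(
                (rec["start"], rec["stop"]),
                rec["channel"],
                data["mean"],
                data["std"],
            )
        )
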