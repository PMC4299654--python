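"""Stimulus-aware stack model: metadata, timeline and tagged frame access.

An episodic two-photon experiment records one sequence of stimuli per
data file ("block"), in randomized order, with a blank gap between
presentations.  This module binds a :class:`~calstack.lazy_stack.LazyStack`
to that experiment structure: a sidecar JSON header carries the spatial
calibration, frame timing and per-block stimulus sequences; from it a
presentation timeline is computed, and every frame can be tagged with
the stimulus on screen while it was acquired (global time, block, time
within stimulus, whether the frame falls inside the analysis window).

Conventions
-----------
* Frame/block indices are 0-based throughout the API.  Inside
  :func:`frame_stimulus_info` records, ``block_index``,
  ``frame_in_block`` and ``presentation_index`` are reported 1-based,
  matching the field convention of the acquisition metadata model.
* A frame belongs to the presentation whose half-open interval
  ``[start, end)`` contains the frame ONSET time.
* Blocks abut exactly in time; dead time is modelled as trailing blank
  within a block.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lazy_stack import DTYPES, LazyStack, open_binary_stack, open_tiff_stack

__all__ = [
    "StackHeader",
    "StimulusTimeline",
    "StimulusStack",
    "UnsupportedFormatError",
    "TimelineOverrunError",
    "open_stack",
    "build_timeline",
    "frame_stimulus_info",
]

_RAW_EXTENSIONS = (".bin", ".raw", ".dat")
_TIFF_EXTENSIONS = (".tif", ".tiff")


class UnsupportedFormatError(ValueError):
    """File extension matches no known stack backend."""


class TimelineOverrunError(ValueError):
    """A block's stimulus sequence does not fit within its frames."""


@dataclass
class StackHeader:
    """Sidecar metadata shared by all blocks of one stack.

    ``stimulus_durations`` and ``use_times`` are indexed by stimulus
    sequence ID (IDs are 1-based: ID ``k`` uses entry ``k - 1``).
    ``use_times[k-1] = [t_start, t_stop]`` delimits, as offsets from
    stimulus onset, the part of each presentation used for analysis.
    """

    n_rows: int
    n_cols: int
    n_channels: int
    dtype: str
    frames_per_file: list[int]
    f_pixels_per_um: float = 1.0
    t_frame_duration: float = 1.0
    f_z_step: float = 0.0
    t_blank_time: float = 0.0
    stimulus_ids_per_block: list[int] = field(default_factory=list)
    sequence_ids_per_block: list[list[int]] = field(default_factory=list)
    stimulus_durations: list[float] = field(default_factory=list)
    use_times: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dtype not in DTYPES:
            raise ValueError(
                f"dtype {self.dtype!r} not one of {sorted(DTYPES)}"
            )
        if min(self.n_rows, self.n_cols, self.n_channels) < 1:
            raise ValueError("n_rows, n_cols, n_channels must be >= 1")
        if not self.frames_per_file or any(n < 1 for n in self.frames_per_file):
            raise ValueError("frames_per_file must be a non-empty list of >= 1")
        if self.t_frame_duration <= 0:
            raise ValueError("t_frame_duration must be > 0")
        if any(d <= 0 for d in self.stimulus_durations):
            raise ValueError("stimulus durations must be > 0")
        if self.t_blank_time < 0:
            raise ValueError("t_blank_time must be >= 0")
        if len(self.use_times) not in (0, len(self.stimulus_durations)):
            raise ValueError("use_times must have one [start, stop] per stimulus")
        for sid_list in self.sequence_ids_per_block:
            for sid in sid_list:
                if not 1 <= sid <= len(self.stimulus_durations):
                    raise ValueError(
                        f"sequence ID {sid} has no stimulus duration entry"
                    )
        for k, row in enumerate(self.use_times):
            t0, t1 = row
            if not (0 <= t0 < t1 <= self.stimulus_durations[k] + 1e-9):
                raise ValueError(
                    f"use_times for stimulus {k + 1} must satisfy "
                    f"0 <= start < stop <= duration"
                )

    def duration_of(self, seq_id: int) -> float:
        return float(self.stimulus_durations[seq_id - 1])

    def use_window_of(self, seq_id: int) -> tuple[float, float]:
        if not self.use_times:
            return (0.0, self.duration_of(seq_id))
        t0, t1 = self.use_times[seq_id - 1]
        return (float(t0), float(t1))

    # -- JSON sidecar ------------------------------------------------------

    @classmethod
    def from_json(cls, path: str) -> "StackHeader":
        with open(path) as fh:
            doc = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in doc.items() if k in known})

    def to_json(self, path: str) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            json.dump(
                doc, fh, indent=1,
                default=lambda o: o.item() if hasattr(o, "item") else list(o),
            )


@dataclass
class StimulusTimeline:
    """All stimulus presentations of a stack, in acquisition order."""

    start_times: np.ndarray  # seconds from first frame of the stack
    end_times: np.ndarray
    presentation_stim_id: np.ndarray  # sequence ID per presentation
    n_stimuli: int

    @property
    def n_presentations(self) -> int:
        return len(self.start_times)


def build_timeline(header: StackHeader) -> StimulusTimeline:
    """Lay out presentations block by block from the header sequences.

    Within a block, presentations run back to back from the block's
    first-frame time, each followed by ``t_blank_time`` of untagged gap.
    Raises :class:`TimelineOverrunError` if a presentation ends after its
    block does.
    """
    starts, ends, sids = [], [], []
    block_start_frame = 0
    for b, nf in enumerate(header.frames_per_file):
        t0 = block_start_frame * header.t_frame_duration
        t_end_block = (block_start_frame + nf) * header.t_frame_duration
        cursor = t0
        seq = (
            header.sequence_ids_per_block[b]
            if b < len(header.sequence_ids_per_block)
            else []
        )
        for sid in seq:
            dur = header.duration_of(sid)
            if cursor + dur > t_end_block + 1e-9:
                raise TimelineOverrunError(
                    f"block {b}: presentation of stimulus {sid} ends at "
                    f"{cursor + dur:.3f} s but the block ends at "
                    f"{t_end_block:.3f} s"
                )
            starts.append(cursor)
            ends.append(cursor + dur)
            sids.append(sid)
            cursor += dur + header.t_blank_time
        block_start_frame += nf
    distinct = {s for seq in header.sequence_ids_per_block for s in seq}
    return StimulusTimeline(
        start_times=np.asarray(starts, dtype=float),
        end_times=np.asarray(ends, dtype=float),
        presentation_stim_id=np.asarray(sids, dtype=int),
        n_stimuli=len(distinct),
    )


def frame_stimulus_info(
    stack: "StimulusStack", frame_indices: Sequence[int] | None = None
) -> pd.DataFrame:
    """Tag frames with block, timing and stimulus information.

    Returns a DataFrame with one row per requested frame (default: all),
    columns ``frame, t_global, block_index, frame_in_block, t_in_block,
    stim_seq_id, t_in_stim, presentation_index, use_frame``.  Frames in
    blank gaps get a null ``stim_seq_id`` and ``use_frame == False``.
    """
    header, timeline = stack.header, stack.timeline
    n_frames = stack.n_frames
    if frame_indices is None:
        frames = np.arange(n_frames)
    else:
        frames = np.asarray(frame_indices, dtype=int)
        if frames.size and (frames.min() < 0 or frames.max() >= n_frames):
            raise IndexError("frame index out of range")
    t_global = frames * header.t_frame_duration
    block_edges = np.cumsum([0] + list(header.frames_per_file))
    block0 = np.searchsorted(block_edges, frames, side="right") - 1
    frame_in_block0 = frames - block_edges[block0]
    t_in_block = frame_in_block0 * header.t_frame_duration

    stim_id = np.full(frames.size, -1, dtype=int)
    pres_idx0 = np.full(frames.size, -1, dtype=int)
    t_in_stim = np.full(frames.size, np.nan)
    use = np.zeros(frames.size, dtype=bool)
    if timeline.n_presentations:
        j = np.searchsorted(timeline.start_times, t_global, side="right") - 1
        valid = (j >= 0) & (t_global < timeline.end_times[np.clip(j, 0, None)])
        jv = j[valid]
        stim_id[valid] = timeline.presentation_stim_id[jv]
        pres_idx0[valid] = jv
        t_in_stim[valid] = t_global[valid] - timeline.start_times[jv]
        for k in np.flatnonzero(valid):
            u0, u1 = header.use_window_of(stim_id[k])
            use[k] = u0 <= t_in_stim[k] < u1

    df = pd.DataFrame(
        {
            "frame": frames,
            "t_global": t_global,
            "block_index": block0 + 1,
            "frame_in_block": frame_in_block0 + 1,
            "t_in_block": t_in_block,
            "stim_seq_id": pd.array(
                [s if s > 0 else None for s in stim_id], dtype="Int64"
            ),
            "t_in_stim": t_in_stim,
            "presentation_index": pd.array(
                [p + 1 if p >= 0 else None for p in pres_idx0], dtype="Int64"
            ),
            "use_frame": use,
        }
    )
    return df


class StimulusStack:
    """A lazy pixel stack bound to its experiment metadata.

    Processed frame access composes, per frame: sub-pixel re-registration
    (when ``frame_shifts`` are assigned) and black-level subtraction
    (when ``black_trace`` is assigned).  Border pixels that sample outside
    the frame after shifting are NaN.
    """

    def __init__(
        self,
        data: LazyStack,
        header: StackHeader,
        timeline: StimulusTimeline | None = None,
    ) -> None:
        if data.shape != (
            header.n_rows,
            header.n_cols,
            sum(header.frames_per_file),
            header.n_channels,
        ):
            raise ValueError("data shape disagrees with header geometry")
        self.data = data
        self.header = header
        self.timeline = timeline if timeline is not None else build_timeline(header)
        self.frame_shifts: np.ndarray | None = None  # (n_frames, 2) of (dy, dx)
        self.black_trace: np.ndarray | None = None  # (n_frames,)
        self.baseline: list = []  # BaselineEntry list (baseline module)
        self.cache_dir: str | None = None
        self._shift_version = 0

    # ------------------------------------------------------------ properties

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    def set_frame_shifts(self, shifts: np.ndarray | None) -> None:
        if shifts is not None:
            shifts = np.asarray(shifts, dtype=float)
            if shifts.shape != (self.n_frames, 2):
                raise ValueError(
                    f"frame_shifts must be ({self.n_frames}, 2), got {shifts.shape}"
                )
            if not np.all(np.isfinite(shifts)):
                raise ValueError("frame_shifts must be finite")
        self.frame_shifts = shifts
        self._shift_version += 1

    def set_black_trace(self, trace: np.ndarray | None) -> None:
        if trace is not None:
            trace = np.asarray(trace, dtype=float)
            if trace.shape != (self.n_frames,):
                raise ValueError("black_trace length must equal n_frames")
            if not np.all(np.isfinite(trace)):
                raise ValueError("black_trace must be finite")
        self.black_trace = trace
        self._shift_version += 1

    # ----------------------------------------------------------------- reads

    def frame_stimulus_info(
        self, frame_indices: Sequence[int] | None = None
    ) -> pd.DataFrame:
        return frame_stimulus_info(self, frame_indices)

    def get_frames(
        self,
        frame_indices: Sequence[int],
        channel: int = 0,
        processed: bool = True,
    ) -> np.ndarray:
        """Return frames ``(n_rows, n_cols, len(frame_indices))``.

        ``processed=False`` returns raw stored values; ``processed=True``
        returns float64 frames re-registered by the assigned shifts and
        black-subtracted, with invalid (border) pixels NaN.
        """
        if not 0 <= channel < self.n_channels:
            raise IndexError(
                f"channel {channel} out of range for {self.n_channels}-channel stack"
            )
        frames = np.asarray(frame_indices, dtype=int)
        raw = self.data.read_region(
            [slice(None), slice(None), frames, channel]
        )[:, :, :, 0]
        if not processed:
            return raw
        out = raw.astype(np.float64)
        if self.frame_shifts is not None:
            from .alignment import apply_shift

            for k, f in enumerate(frames):
                dy, dx = self.frame_shifts[f]
                if dy != 0.0 or dx != 0.0:
                    out[:, :, k] = apply_shift(out[:, :, k], (dy, dx))
        if self.black_trace is not None:
            out = out - self.black_trace[frames][None, None, :]
        return out


def open_stack(paths: Sequence[str], header_path: str) -> StimulusStack:
    """Open a multi-block stack plus its JSON sidecar header.

    Raw-binary blocks (``.bin/.raw/.dat``) take their geometry from the
    header; TIFF blocks (``.tif/.tiff``) are validated against it.  No
    pixel data is read.
    """
    header = StackHeader.from_json(header_path)
    paths = [os.fspath(p) for p in paths]
    exts = {os.path.splitext(p)[1].lower() for p in paths}
    if exts <= set(_RAW_EXTENSIONS):
        data = open_binary_stack(paths, header)
    elif exts <= set(_TIFF_EXTENSIONS):
        data = open_tiff_stack(paths)
        expect = (
            header.n_rows,
            header.n_cols,
            sum(header.frames_per_file),
            header.n_channels,
        )
        if data.shape != expect:
            raise ValueError(
                f"TIFF geometry {data.shape} disagrees with header {expect}"
            )
    else:
        supported = ", ".join(_RAW_EXTENSIONS + _TIFF_EXTENSIONS)
        raise UnsupportedFormatError(
            f"unsupported stack extension(s) {sorted(exts)}; supported: {supported}"
        )
    return StimulusStack(data, header)
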