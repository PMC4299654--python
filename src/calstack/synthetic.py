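"""Synthetic two-photon experiment generator with full ground truth.

Emulates an episodic visual-cortex recording end to end, on disk, in
the package's own stack formats: planted cells with direction-tuned
calcium transients, baseline fluorescence, instrument black level,
shot-like Gaussian noise, rigid frame motion, and per-block randomized
stimulus sequences — everything the analysis pipeline is supposed to
undo, with the true values recorded.

Defaults follow a typical cortical drifting-grating session: 128 x 128
px frames at 7.81 Hz, 8-bit, two channels, 16 drift directions of 2 s
each presented in independent random order in every block, 5 blocks
(hence 5 trials per direction), GCaMP-like transients with
instantaneous rise and exponential decay (tau = 0.6 s).

The pixel model, per frame at time t (channel 1):

    value = black + bg + sum_i mask_i * F0 * (1 + dff_i(t)) + noise
    dff_i(t) = sum_p a_i * max(0, cos(theta_p - pref_i)) * exp(-(t - t_p)/tau)

over presentations p with onset t_p <= t; the composed frame is then
rigidly displaced along the motion path by the same bilinear operator
the aligner inverts, and quantized to the target dtype with clipping.
Channel 2 carries no cells (structural/counterstain channel), which is
what the difference-image detector exploits.

:class:`GroundTruth` resolves every random choice (orders, shifts,
centers, per-presentation ideal peak dF/F0 including decay tails), so
expected outputs of every pipeline stage have closed forms that never
touch the code under test.
"""

from __future__ import annotations

import json
import os
import struct
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .alignment import apply_shift
from .stack_model import StackHeader, open_stack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_experiment",
    "generate_and_open",
    "write_imagej_fixture",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment (all rates in Hz, times s,
    lengths px, fluorescence in raw dtype units above black)."""

    n_rows: int = 128
    n_cols: int = 128
    n_channels: int = 2
    dtype: str = "u8"
    frame_rate: float = 7.81
    n_blocks: int = 5
    n_stimuli: int = 16
    stimulus_duration: float = 2.0
    blank_time: float = 1.0
    use_times: list | None = None  # [start, stop] per stimulus; None = full
    frames_per_block: list | None = None  # None: computed from the timeline
    orders: list | None = None  # forced per-block sequences ([] = blank block)
    n_cells: int = 10
    cell_centers: list | None = None  # [(row, col), ...]; None: placed
    cell_radius: float = 4.0
    cell_profile: str = "gaussian"  # "gaussian" (sigma = radius/2) | "disc"
    amplitudes: float | list = 1.0  # peak dF/F0 at the preferred direction
    preferred_directions: list | None = None  # deg; None: cycled over stimuli
    tau: float = 0.6
    f0_level: float = 60.0
    background_level: float = 0.0
    black_level: float = 10.0
    noise_sd: float = 0.0
    motion_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_channels, self.n_blocks) < 1:
            raise ValueError("dims and n_blocks must be >= 1")
        if self.frame_rate <= 0 or self.tau <= 0:
            raise ValueError("frame_rate and tau must be > 0")
        if self.n_stimuli > 0 and self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be > 0")
        if self.blank_time < 0 or self.noise_sd < 0 or self.motion_amplitude < 0:
            raise ValueError("blank_time, noise_sd, motion_amplitude must be >= 0")
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if np.any(amps < 0):
            raise ValueError("amplitudes must be >= 0")
        if self.n_cells < 0 or self.cell_radius <= 0:
            raise ValueError("n_cells >= 0 and cell_radius > 0 required")
        if self.cell_profile not in ("gaussian", "disc"):
            raise ValueError("cell_profile must be 'gaussian' or 'disc'")

    @property
    def t_frame(self) -> float:
        return 1.0 / self.frame_rate

    def directions_deg(self) -> np.ndarray:
        """Drift direction shown by stimulus ID k (= directions[k-1])."""
        return np.arange(self.n_stimuli) * 360.0 / max(self.n_stimuli, 1)


@dataclass
class GroundTruth:
    """Every random choice of :func:`generate_experiment`, resolved."""

    config: dict
    orders_per_block: list  # stimulus-ID sequences actually used
    frames_per_block: list
    shifts: list  # (n_frames, 2) content displacement (dy, dx) per frame
    cell_centers: list
    cell_radius: float
    amplitudes: list
    preferred_directions: list
    directions_deg: list
    presentation_stim_id: list
    presentation_start_times: list
    ideal_peak_dff: list  # (n_cells, n_presentations), decay tails included
    black_region: list  # linear pixel indices guaranteed cell-free

    @property
    def n_frames(self) -> int:
        return int(sum(self.frames_per_block))

    def cell_masks(self, dims: tuple[int, int]) -> list[np.ndarray]:
        """Linear pixel indices of each planted cell disc."""
        nr, nc = dims
        out = []
        for cy, cx in self.cell_centers:
            rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
            m = (rr - cy) ** 2 + (cc - cx) ** 2 <= self.cell_radius**2
            out.append(np.flatnonzero(m.ravel()))
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                asdict(self), fh,
                default=lambda o: o.item() if hasattr(o, "item") else list(o),
            )

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _place_cells(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random non-overlapping centers with a border margin."""
    if cfg.cell_centers is not None:
        return np.asarray(cfg.cell_centers, dtype=float)
    margin = cfg.cell_radius + 2
    min_sep = 3.0 * cfg.cell_radius
    centers: list = []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"cannot place {cfg.n_cells} cells of radius "
                f"{cfg.cell_radius} in {cfg.n_rows} x {cfg.n_cols}"
            )
        p = rng.uniform(
            [margin, margin], [cfg.n_rows - margin, cfg.n_cols - margin]
        )
        if all(np.hypot(*(p - q)) >= min_sep for q in centers):
            centers.append(p)
    return np.asarray(centers)


def _dtype_info(dtype: str):
    from .lazy_stack import DTYPES

    np_dtype = DTYPES[dtype]
    if np.issubdtype(np_dtype, np.integer):
        info = np.iinfo(np_dtype)
        return np_dtype, info.min, info.max
    return np_dtype, -np.inf, np.inf


def generate_experiment(
    cfg: SimConfig, out_dir: str, file_format: str = "raw"
) -> tuple[list[str], str, GroundTruth]:
    """Write a synthetic multi-block stack and its ground truth.

    Returns ``(block_paths, header_path, ground_truth)``; also writes
    ``ground_truth.json`` beside the header.  Identical config (including
    seed) produces byte-identical files.
    """
    if file_format not in ("raw", "tiff"):
        raise ValueError(f"file_format must be 'raw' or 'tiff', got {file_format!r}")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    t_frame = cfg.t_frame

    # --- stimulus orders and timeline (independent arithmetic) ------------
    if cfg.orders is not None:
        if len(cfg.orders) != cfg.n_blocks:
            raise ValueError("orders must give one sequence per block")
        orders = [[int(s) for s in seq] for seq in cfg.orders]
        for seq in orders:
            if any(not 1 <= s <= cfg.n_stimuli for s in seq):
                raise ValueError("forced order contains an unknown stimulus ID")
    else:
        orders = [
            (rng.permutation(cfg.n_stimuli) + 1).tolist() if cfg.n_stimuli else []
            for _ in range(cfg.n_blocks)
        ]
    if cfg.frames_per_block is not None:
        frames_per_block = [int(n) for n in cfg.frames_per_block]
    else:
        # per-block frame count covers that block's own sequence; an empty
        # (all-blank) block still gets at least 2 s of frames
        min_frames = max(1, int(np.ceil(2.0 / t_frame)))
        frames_per_block = [
            max(
                min_frames,
                int(np.ceil(
                    len(seq) * (cfg.stimulus_duration + cfg.blank_time) / t_frame
                )),
            )
            for seq in orders
        ]
    n_frames = sum(frames_per_block)

    pres_sid, pres_start = [], []
    frame0 = 0
    for b, nf in enumerate(frames_per_block):
        t0 = frame0 * t_frame
        cursor = t0
        for sid in orders[b]:
            pres_sid.append(int(sid))
            pres_start.append(cursor)
            cursor += cfg.stimulus_duration + cfg.blank_time
        frame0 += nf

    # --- cells -------------------------------------------------------------
    centers = _place_cells(cfg, rng)
    amps = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.amplitudes, dtype=float)), (cfg.n_cells,)
    ).copy()
    dirs = cfg.directions_deg()
    if cfg.preferred_directions is not None:
        prefs = np.asarray(cfg.preferred_directions, dtype=float)
    elif cfg.n_stimuli:
        prefs = dirs[np.arange(cfg.n_cells) % cfg.n_stimuli]
    else:
        prefs = np.zeros(cfg.n_cells)

    rr, cc = np.meshgrid(
        np.arange(cfg.n_rows), np.arange(cfg.n_cols), indexing="ij"
    )
    occupied = np.zeros((cfg.n_rows, cfg.n_cols), dtype=bool)
    cell_pix: list[np.ndarray] = []  # flat pixel indices per cell
    cell_prof: list[np.ndarray] = []  # F0 profile values on those pixels
    sigma = cfg.cell_radius / 2.0
    for cy, cx in centers:
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        m = d2 <= cfg.cell_radius**2
        idx = np.flatnonzero(m.ravel())
        if cfg.cell_profile == "gaussian":
            prof = cfg.f0_level * np.exp(-d2.ravel()[idx] / (2.0 * sigma**2))
        else:
            prof = np.full(idx.size, cfg.f0_level)
        cell_pix.append(idx)
        cell_prof.append(prof)
        occupied |= m

    # a cell-free region for black-level estimation; generous so the
    # per-frame black estimate contributes negligible noise to traces
    free = np.flatnonzero(~occupied.ravel())
    black_region = free[: min(256, free.size)].tolist()

    # --- per-cell dF/F0 traces over frame onset times ----------------------
    t = np.arange(n_frames) * t_frame
    dff = np.zeros((cfg.n_cells, n_frames))
    tuning = np.zeros((cfg.n_cells, len(pres_sid)))
    for p, (sid, ts) in enumerate(zip(pres_sid, pres_start)):
        theta = np.deg2rad(dirs[sid - 1] - prefs)
        tuning[:, p] = np.maximum(0.0, np.cos(theta))
        active = t >= ts - 1e-9
        decay = np.exp(-(t[active] - ts) / cfg.tau)
        dff[:, active] += (amps * tuning[:, p])[:, None] * decay[None, :]

    # ideal peak dF/F0 per (cell, presentation): max of the composed trace
    # over that presentation's use-window frames (tails included)
    use = cfg.use_times
    ideal_peak = np.full((cfg.n_cells, len(pres_sid)), np.nan)
    for p, (sid, ts) in enumerate(zip(pres_sid, pres_start)):
        u0, u1 = (0.0, cfg.stimulus_duration) if use is None else use[sid - 1]
        t_rel = t - ts
        sel = (
            (t_rel >= u0 - 1e-9)
            & (t_rel < u1 - 1e-9)
            & (t_rel < cfg.stimulus_duration - 1e-9)
        )
        if sel.any():
            ideal_peak[:, p] = dff[:, sel].max(axis=1)

    # --- motion path --------------------------------------------------------
    if cfg.motion_amplitude > 0 and n_frames > 1:
        phase = np.arange(n_frames) / n_frames
        shifts = np.column_stack(
            [
                cfg.motion_amplitude * np.sin(2 * np.pi * phase),
                cfg.motion_amplitude * 0.5 * np.sin(4 * np.pi * phase),
            ]
        )
    else:
        shifts = np.zeros((n_frames, 2))

    # --- compose and write ---------------------------------------------------
    np_dtype, vmin, vmax = _dtype_info(cfg.dtype)
    base = cfg.black_level + cfg.background_level
    static = np.full((cfg.n_rows, cfg.n_cols), base)

    paths = []
    tiff_writer = None
    frame0 = 0
    chunk = 128
    for b, nf in enumerate(frames_per_block):
        if file_format == "raw":
            path = os.path.join(out_dir, f"block_{b:03d}.bin")
            fh = open(path, "wb")
        else:
            import tifffile

            path = os.path.join(out_dir, f"block_{b:03d}.tif")
            fh = None
            tiff_writer = tifffile.TiffWriter(path)
        paths.append(path)
        for lo in range(0, nf, chunk):
            hi = min(lo + chunk, nf)
            fidx = np.arange(frame0 + lo, frame0 + hi)
            block = np.empty(
                (hi - lo, cfg.n_rows, cfg.n_cols, cfg.n_channels)
            )
            for k, f in enumerate(fidx):
                # channel 1 carries the cells, modulated by dF/F0
                mod = np.zeros(static.size)
                for idx, prof, tr in zip(cell_pix, cell_prof, dff[:, f]):
                    mod[idx] += prof * (1.0 + tr)
                block[k, :, :, 0] = static + mod.reshape(static.shape)
                for ch in range(1, cfg.n_channels):
                    block[k, :, :, ch] = static
            if cfg.noise_sd > 0:
                block = block + rng.normal(0.0, cfg.noise_sd, size=block.shape)
            for k, f in enumerate(fidx):
                dy, dx = shifts[f]
                if dy != 0.0 or dx != 0.0:
                    for ch in range(cfg.n_channels):
                        block[k, :, :, ch] = apply_shift(
                            block[k, :, :, ch], (-dy, -dx), fill=base
                        )
            if np.issubdtype(np_dtype, np.integer):
                block = np.clip(np.rint(block), vmin, vmax)
            block = block.astype(np_dtype)
            if file_format == "raw":
                fh.write(block.tobytes())
            else:
                for k in range(block.shape[0]):
                    page = block[k, :, :, 0] if cfg.n_channels == 1 else block[k]
                    tiff_writer.write(
                        page, photometric="minisblack", contiguous=False
                    )
        if fh is not None:
            fh.close()
        if tiff_writer is not None:
            tiff_writer.close()
            tiff_writer = None
        frame0 += nf

    header = StackHeader(
        n_rows=cfg.n_rows,
        n_cols=cfg.n_cols,
        n_channels=cfg.n_channels,
        dtype=cfg.dtype,
        frames_per_file=frames_per_block,
        t_frame_duration=t_frame,
        t_blank_time=cfg.blank_time,
        stimulus_ids_per_block=list(range(1, cfg.n_blocks + 1)),
        sequence_ids_per_block=orders,
        stimulus_durations=[cfg.stimulus_duration] * cfg.n_stimuli,
        use_times=(
            [list(u) for u in cfg.use_times] if cfg.use_times is not None else []
        ),
    )
    header_path = os.path.join(out_dir, "stack_header.json")
    header.to_json(header_path)

    gt = GroundTruth(
        config=asdict(cfg),
        orders_per_block=orders,
        frames_per_block=frames_per_block,
        shifts=shifts.tolist(),
        cell_centers=centers.tolist(),
        cell_radius=cfg.cell_radius,
        amplitudes=amps.tolist(),
        preferred_directions=prefs.tolist(),
        directions_deg=dirs.tolist(),
        presentation_stim_id=pres_sid,
        presentation_start_times=pres_start,
        ideal_peak_dff=ideal_peak.tolist(),
        black_region=black_region,
    )
    gt.to_json(os.path.join(out_dir, "ground_truth.json"))
    return paths, header_path, gt


def generate_and_open(cfg: SimConfig, out_dir: str, file_format: str = "raw"):
    """Generate an experiment and open it as a StimulusStack."""
    paths, header_path, gt = generate_experiment(cfg, out_dir, file_format)
    return open_stack(paths, header_path), gt


# -------------------------------------------------------- ImageJ fixtures


_IJ_TYPE_CODE = {"rect": 1, "oval": 2, "polygon": 0, "freehand": 7}


def _roi_bytes(shape: dict) -> bytes:
    """Encode one shape spec as an ImageJ .roi payload."""
    kind = shape["type"]
    if kind not in _IJ_TYPE_CODE:
        raise ValueError(f"unsupported ROI shape {kind!r}")
    if kind in ("rect", "oval"):
        top, left = int(shape["top"]), int(shape["left"])
        bottom, right = int(shape["bottom"]), int(shape["right"])
        n = 0
        coords = b""
    else:
        xs = np.asarray(shape["xs"], dtype=int)
        ys = np.asarray(shape["ys"], dtype=int)
        if xs.size != ys.size or xs.size < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertex pairs")
        left, top = int(xs.min()), int(ys.min())
        right, bottom = int(xs.max()), int(ys.max())
        n = xs.size
        rel = np.concatenate([xs - left, ys - top]).astype(">i2")
        coords = rel.tobytes()
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = _IJ_TYPE_CODE[kind]
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    return bytes(header) + coords


def write_imagej_fixture(shapes: Sequence[dict], path: str) -> str:
    """Write shape specs as an ImageJ ``.roi`` file or ``.zip`` archive.

    Each spec is a dict: ``{"type": "rect"|"oval", "top", "left",
    "bottom", "right"}`` or ``{"type": "polygon"|"freehand", "xs", "ys"}``
    (ImageJ coordinates, x = column).  A ``.zip`` path may hold any
    number of shapes; a ``.roi`` path exactly one.
    """
    path = os.fspath(path)
    if path.lower().endswith(".zip"):
        with zipfile.ZipFile(path, "w") as zf:
            for k, shape in enumerate(shapes):
                info = zipfile.ZipInfo(f"roi_{k:03d}.roi")
                zf.writestr(info, _roi_bytes(shape))
        return path
    if len(shapes) != 1:
        raise ValueError("a .roi path holds exactly one ROI; use .zip")
    with open(path, "wb") as fh:
        fh.write(_roi_bytes(shapes[0]))
    return path
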