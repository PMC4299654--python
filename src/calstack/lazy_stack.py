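"""Disk-backed lazy tensors for multi-file imaging stacks.

Two-photon movies routinely exceed RAM (a typical session here is a
128 x 128 x ~7000 x 2 uint8 stack, ~240 MB, split across several files;
TIFF sessions run to the gigabyte).  :class:`LazyStack` exposes such a
multi-file recording as a single 4-D array ``(rows, cols, frames,
channels)`` without ever loading it whole: pixel data are read from disk
only when a region is requested, axis permutation and affine value
transforms (negation, scaling, offsets) are O(1) metadata operations,
and whole-stack processing runs slice-by-slice under a bounded memory
footprint.

Two storage backends are supported:

* a documented raw-binary dialect -- little-endian, channel-fastest,
  then columns, then rows, then frames, i.e. each frame is one
  contiguous ``rows x cols x channels`` span; and
* baseline grayscale multi-frame TIFF (read-only; directory offsets are
  parsed once at open time via :mod:`tifffile`).
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BlockDescriptor",
    "LazyStack",
    "SizeMismatchError",
    "DimensionMismatchError",
    "ReadOnlyStackError",
    "BoundsError",
    "DTYPES",
    "open_binary_stack",
    "open_tiff_stack",
    "create_temp_stack",
    "storage_bytes",
]

#: Supported element types, keyed by the short names used in sidecar headers.
DTYPES = {
    "u8": np.dtype("<u1"),
    "u16": np.dtype("<u2"),
    "i16": np.dtype("<i2"),
    "f32": np.dtype("<f4"),
    "f64": np.dtype("<f8"),
}


class SizeMismatchError(ValueError):
    """A data file is shorter than its declared geometry requires."""


class DimensionMismatchError(ValueError):
    """Blocks of one stack disagree on frame dimensions or dtype."""


class ReadOnlyStackError(PermissionError):
    """Write attempted on a read-only (e.g. TIFF-backed) stack."""


class BoundsError(IndexError):
    """An index fell outside the stack shape; names the offending axis."""


@dataclass
class BlockDescriptor:
    """One contiguous run of frames stored in a single file."""

    path: str
    byte_offset: int
    n_frames: int
    backend: str  # "raw" | "tiff"
    _tiff: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("block must contain at least one frame")
        if self.byte_offset < 0:
            raise ValueError("byte_offset must be >= 0")
        if self.backend not in ("raw", "tiff"):
            raise ValueError(f"unknown backend {self.backend!r}")


class _IOStats:
    """Shared read-accounting between a stack and all views derived from it."""

    __slots__ = ("block_reads", "max_read_elements")

    def __init__(self) -> None:
        self.block_reads = 0
        self.max_read_elements = 0

    def record(self, n_elements: int) -> None:
        self.block_reads += 1
        if n_elements > self.max_read_elements:
            self.max_read_elements = n_elements


def _normalize_index(idx, size: int, axis: int) -> np.ndarray:
    """Turn one per-axis selector (int, slice, range pair, sequence) into indices."""
    if isinstance(idx, slice):
        out = np.arange(*idx.indices(size))
    elif isinstance(idx, (int, np.integer)):
        out = np.asarray([int(idx)])
    else:
        out = np.asarray(idx, dtype=np.intp).ravel()
    if out.size and (out.min() < -size or out.max() >= size):
        bad = out[(out < -size) | (out >= size)][0]
        raise BoundsError(f"index {bad} out of range for axis {axis} of size {size}")
    return np.where(out < 0, out + size, out).astype(np.intp)


class LazyStack:
    """A lazily-read 4-D pixel tensor spanning ordered on-disk blocks.

    Native axis order is ``(rows, cols, frames, channels)``; ``axis_order``
    maps the user-visible axes onto the native ones.  ``value_transform``
    ``(a, b)`` is applied read-side as ``a*x + b``; writes store raw dtype
    values.  ``io_read_count`` counts block reads and is shared between a
    stack and every view produced by :meth:`permute_axes` /
    :meth:`scale_offset`, so laziness is directly observable.
    """

    # frame axis is native axis 2 throughout
    _FRAME_AXIS = 2

    def __init__(
        self,
        native_shape: tuple[int, int, int, int],
        dtype: np.dtype,
        blocks: Sequence[BlockDescriptor],
        *,
        axis_order: tuple[int, int, int, int] = (0, 1, 2, 3),
        value_transform: tuple[float, float] = (1.0, 0.0),
        writable: bool = False,
        io_stats: _IOStats | None = None,
    ) -> None:
        native_shape = tuple(int(s) for s in native_shape)
        if len(native_shape) != 4 or any(s < 1 for s in native_shape):
            raise ValueError("native_shape must be four integers >= 1")
        blocks = list(blocks)
        total = sum(b.n_frames for b in blocks)
        if total != native_shape[self._FRAME_AXIS]:
            raise DimensionMismatchError(
                f"blocks supply {total} frames, shape declares "
                f"{native_shape[self._FRAME_AXIS]}"
            )
        self.native_shape = native_shape
        self.dtype = np.dtype(dtype)
        self.blocks = blocks
        self.axis_order = tuple(axis_order)
        self.value_transform = (float(value_transform[0]), float(value_transform[1]))
        self.writable = bool(writable)
        self._io = io_stats if io_stats is not None else _IOStats()
        self._block_starts = np.cumsum([0] + [b.n_frames for b in blocks])

    # ------------------------------------------------------------------ views

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.native_shape[a] for a in self.axis_order)

    @property
    def io_read_count(self) -> int:
        return self._io.block_reads

    @property
    def max_read_elements(self) -> int:
        return self._io.max_read_elements

    def permute_axes(self, order: Sequence[int]) -> "LazyStack":
        """O(1) axis permutation (relative to the current visible order)."""
        order = tuple(int(a) for a in order)
        if sorted(order) != [0, 1, 2, 3]:
            raise ValueError(f"{order!r} is not a permutation of 4 axes")
        new_order = tuple(self.axis_order[a] for a in order)
        return self._view(axis_order=new_order)

    def scale_offset(self, a: float, b: float) -> "LazyStack":
        """O(1) affine value transform; composes with any existing transform.

        Reads return ``a * (previous transform applied to x) + b``.
        """
        a0, b0 = self.value_transform
        return self._view(value_transform=(a * a0, a * b0 + b))

    def _view(self, **overrides) -> "LazyStack":
        kw = dict(
            axis_order=self.axis_order,
            value_transform=self.value_transform,
            writable=self.writable,
            io_stats=self._io,
        )
        kw.update(overrides)
        return LazyStack(self.native_shape, self.dtype, self.blocks, **kw)

    # ------------------------------------------------------------------ reads

    def read_region(self, ranges: Sequence) -> np.ndarray:
        """Read a region given per-axis selectors in the current axis order.

        Each selector may be an int, a slice, or a sequence of indices.
        Only blocks overlapping the requested frames are touched.  Returns
        the stored values with the value transform applied (native dtype
        for the identity transform, float64 otherwise).
        """
        if len(ranges) != 4:
            raise ValueError("read_region expects one selector per axis (4)")
        vis = [
            _normalize_index(r, self.native_shape[self.axis_order[i]], i)
            for i, r in enumerate(ranges)
        ]
        # selectors re-expressed on native axes
        native_sel: list[np.ndarray] = [None] * 4
        for i, ax in enumerate(self.axis_order):
            native_sel[ax] = vis[i]
        raw = self._read_native(native_sel)
        out = raw.transpose(self.axis_order)
        a, b = self.value_transform
        if (a, b) != (1.0, 0.0):
            out = a * out.astype(np.float64) + b
        return out

    def _read_native(self, sel: list[np.ndarray]) -> np.ndarray:
        rows, cols, frames, chans = sel
        out = np.empty(
            (rows.size, cols.size, frames.size, chans.size), dtype=self.dtype
        )
        order = np.argsort(frames, kind="stable")
        sorted_frames = frames[order]
        # walk blocks; gather the frames each block owns in one access
        for bi, block in enumerate(self.blocks):
            lo, hi = self._block_starts[bi], self._block_starts[bi + 1]
            mask = (sorted_frames >= lo) & (sorted_frames < hi)
            if not mask.any():
                continue
            local = sorted_frames[mask] - lo
            data = self._read_block(block, local, rows, cols, chans)
            self._io.record(data.size)
            out[:, :, order[mask], :] = np.moveaxis(data, 0, 2)
        return out

    def _read_block(
        self,
        block: BlockDescriptor,
        local_frames: np.ndarray,
        rows: np.ndarray,
        cols: np.ndarray,
        chans: np.ndarray,
    ) -> np.ndarray:
        """Return ``(n_local_frames, n_rows, n_cols, n_chans)`` raw values."""
        nr, nc, _, nch = self.native_shape
        if block.backend == "raw":
            mm = np.memmap(
                block.path,
                dtype=self.dtype,
                mode="r",
                offset=block.byte_offset,
                shape=(block.n_frames, nr, nc, nch),
            )
            data = mm[np.ix_(local_frames, rows, cols, chans)].copy()
            del mm
            return data
        # TIFF: read the needed pages through the directory parsed at open
        pages = block._tiff.pages
        frames_out = np.empty(
            (local_frames.size, rows.size, cols.size, chans.size), dtype=self.dtype
        )
        for k, f in enumerate(local_frames):
            page = np.asarray(pages[int(f)].asarray())
            if page.ndim == 2:
                page = page[:, :, None]
            frames_out[k] = page[np.ix_(rows, cols, chans)]
        return frames_out

    # ----------------------------------------------------------------- writes

    def write_region(self, ranges: Sequence, values: np.ndarray) -> None:
        """Write ``values`` into the region (raw-binary backend only).

        Values are stored as raw dtype; the read-side value transform is
        deliberately not inverted.  Out-of-range values for integer dtypes
        are clipped to the dtype limits with a warning (acquisition-style
        saturation rather than wraparound).
        """
        if not self.writable:
            raise ReadOnlyStackError("stack is read-only")
        if len(ranges) != 4:
            raise ValueError("write_region expects one selector per axis (4)")
        vis = [
            _normalize_index(r, self.native_shape[self.axis_order[i]], i)
            for i, r in enumerate(ranges)
        ]
        target_shape = tuple(v.size for v in vis)
        values = np.broadcast_to(np.asarray(values), target_shape)
        native_sel: list[np.ndarray] = [None] * 4
        for i, ax in enumerate(self.axis_order):
            native_sel[ax] = vis[i]
        inv = np.argsort(self.axis_order)
        native_vals = values.transpose(tuple(inv))
        if np.issubdtype(self.dtype, np.integer):
            info = np.iinfo(self.dtype)
            if np.any(native_vals < info.min) or np.any(native_vals > info.max):
                warnings.warn(
                    f"values outside {self.dtype} range clipped to "
                    f"[{info.min}, {info.max}]",
                    RuntimeWarning,
                    stacklevel=2,
                )
                native_vals = np.clip(native_vals, info.min, info.max)
        native_vals = native_vals.astype(self.dtype)
        rows, cols, frames, chans = native_sel
        nr, nc, _, nch = self.native_shape
        order = np.argsort(frames, kind="stable")
        sorted_frames = frames[order]
        for bi, block in enumerate(self.blocks):
            lo, hi = self._block_starts[bi], self._block_starts[bi + 1]
            mask = (sorted_frames >= lo) & (sorted_frames < hi)
            if not mask.any():
                continue
            local = sorted_frames[mask] - lo
            mm = np.memmap(
                block.path,
                dtype=self.dtype,
                mode="r+",
                offset=block.byte_offset,
                shape=(block.n_frames, nr, nc, nch),
            )
            chunk = np.moveaxis(native_vals[:, :, order[mask], :], 2, 0)
            mm[np.ix_(local, rows, cols, chans)] = chunk
            mm.flush()
            del mm

    # ------------------------------------------------------------ slice apply

    def slice_apply(
        self,
        fn: Callable[[np.ndarray], np.ndarray],
        axis: int,
        *,
        reduce: bool = False,
        out_dir: str | None = None,
    ):
        """Apply ``fn`` to every slice along ``axis`` under bounded memory.

        In mapping mode (default) ``fn`` must return a slice of the same
        shape; results stream into a writable temporary raw-binary stack
        (float64) so peak resident memory stays at one slice plus constant
        overhead.  With ``reduce=True`` the per-slice return values are
        collected into an array instead.
        """
        n = self.shape[axis]
        slice_shape = tuple(s for i, s in enumerate(self.shape) if i != axis)
        result_stack = None
        reduced = []
        for i in range(n):
            sel = [slice(None)] * 4
            sel[axis] = i
            piece = self.read_region(sel)
            piece3 = piece.reshape(slice_shape)
            res = fn(piece3)
            if reduce:
                reduced.append(res)
                continue
            res = np.asarray(res)
            if res.shape != slice_shape:
                raise ValueError(
                    f"slice function returned shape {res.shape}, expected "
                    f"{slice_shape}, at slice {i}"
                )
            if result_stack is None:
                result_stack = create_temp_stack(self.shape, "f64", dir=out_dir)
            sel_shape = list(slice_shape)
            sel_shape.insert(axis, 1)
            result_stack.write_region(sel, res.reshape(sel_shape))
        if reduce:
            return np.asarray(reduced)
        return result_stack


# ---------------------------------------------------------------------- opens


def _expected_bytes(header, n_frames: int) -> int:
    dtype = DTYPES[header.dtype] if isinstance(header.dtype, str) else np.dtype(header.dtype)
    return n_frames * header.n_rows * header.n_cols * header.n_channels * dtype.itemsize


def open_binary_stack(paths: Sequence[str], header) -> LazyStack:
    """Open ordered raw-binary files as one concatenated lazy stack.

    ``header`` supplies geometry: attributes ``n_rows``, ``n_cols``,
    ``n_channels``, ``dtype`` (short name or numpy dtype) and
    ``frames_per_file``.  No pixel data is read.
    """
    paths = [os.fspath(p) for p in paths]
    if len(paths) != len(header.frames_per_file):
        raise DimensionMismatchError(
            f"{len(paths)} files given but header lists "
            f"{len(header.frames_per_file)} blocks"
        )
    dtype = DTYPES[header.dtype] if isinstance(header.dtype, str) else np.dtype(header.dtype)
    blocks = []
    for path, nf in zip(paths, header.frames_per_file):
        need = _expected_bytes(header, nf)
        have = os.path.getsize(path)
        if have < need:
            raise SizeMismatchError(
                f"file {path!r} holds {have} bytes but geometry requires {need}"
            )
        blocks.append(BlockDescriptor(path, 0, int(nf), "raw"))
    shape = (
        header.n_rows,
        header.n_cols,
        int(sum(header.frames_per_file)),
        header.n_channels,
    )
    return LazyStack(shape, dtype, blocks, writable=True)


def open_tiff_stack(paths: Sequence[str]) -> LazyStack:
    """Open ordered multi-frame TIFF files as one read-only lazy stack.

    Directories are parsed once here; reads go straight to the cached
    page offsets.  All frames must share dimensions and bit depth.
    Grayscale baseline TIFF with at most 2 samples per pixel.
    """
    import tifffile

    paths = [os.fspath(p) for p in paths]
    if not paths:
        raise ValueError("no TIFF files given")
    blocks = []
    ref = None  # (rows, cols, channels, dtype)
    for path in paths:
        tf = tifffile.TiffFile(path)
        pages = tf.pages
        first = pages[0]
        spp = first.samplesperpixel
        if spp > 2:
            raise DimensionMismatchError(
                f"{path!r}: {spp} samples/pixel unsupported (max 2)"
            )
        geom = (first.imagelength, first.imagewidth, spp, np.dtype(first.dtype))
        for p in pages:
            if (p.imagelength, p.imagewidth, p.samplesperpixel, np.dtype(p.dtype)) != geom:
                raise DimensionMismatchError(
                    f"{path!r}: frame dimensions/bit depth vary within the file"
                )
        if ref is None:
            ref = geom
        elif geom != ref:
            raise DimensionMismatchError(
                f"{path!r}: frames {geom[:3]} do not match first file {ref[:3]}"
            )
        blocks.append(
            BlockDescriptor(path, 0, len(pages), "tiff", _tiff=tf)
        )
    rows, cols, chans, dtype = ref
    shape = (int(rows), int(cols), sum(b.n_frames for b in blocks), int(chans))
    return LazyStack(shape, dtype, blocks, writable=False)


def create_temp_stack(
    shape: Sequence[int], dtype="f64", *, dir: str | None = None
) -> LazyStack:
    """Create a writable zero-filled raw-binary stack in a temporary file."""
    np_dtype = DTYPES[dtype] if isinstance(dtype, str) else np.dtype(dtype)
    shape = tuple(int(s) for s in shape)
    fd, path = tempfile.mkstemp(suffix=".calstack.bin", dir=dir)
    n_bytes = int(np.prod(shape)) * np_dtype.itemsize
    os.ftruncate(fd, n_bytes)
    os.close(fd)
    blocks = [BlockDescriptor(path, 0, shape[2], "raw")]
    return LazyStack(shape, np_dtype, blocks, writable=True)


def storage_bytes(shape: Sequence[int], bits_per_element: int) -> int:
    """Raw data bytes for a stack of the given shape and element width."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 4 or any(s < 1 for s in shape):
        raise ValueError("shape must be four integers >= 1")
    if bits_per_element not in (8, 16, 32, 64):
        raise ValueError("bits_per_element must be one of 8, 16, 32, 64")
    return int(np.prod(shape, dtype=np.int64)) * bits_per_element // 8
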