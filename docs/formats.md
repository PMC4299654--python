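# On-disk formats

## Raw-binary stack dialect

Each block file holds frames back to back with no per-file header.
Element order is little-endian, **channel-fastest**: for each frame,
pixels are laid out row by row, and within a pixel the channels are
interleaved.  Equivalently, a block containing `F` frames is the C-order
byte image of an array of shape `(F, n_rows, n_cols, n_channels)`.
A single frame is therefore one contiguous span of
`n_rows * n_cols * n_channels * bytes_per_element` bytes.

Supported element types: `u8`, `u16`, `i16`, `f32`, `f64`
(little-endian).

## Sidecar header (JSON)

One JSON document per stack, shared by all blocks.  Fields:

| field | type | meaning |
|---|---|---|
| `n_rows` | int | frame height, px |
| `n_cols` | int | frame width, px |
| `n_channels` | int | channels per pixel |
| `dtype` | str | element type (`u8`, `u16`, `i16`, `f32`, `f64`) |
| `frames_per_file` | list[int] | frame count of each block, in order |
| `f_pixels_per_um` | float | spatial calibration, px/µm (x and y) |
| `t_frame_duration` | float | acquisition time per frame, s |
| `f_z_step` | float | z spacing between frames, µm (0 for planar) |
| `t_blank_time` | float | blank gap between stimulus presentations, s |
| `stimulus_ids_per_block` | list[int] | stimulus ID of each block (one sequence per block) |
| `sequence_ids_per_block` | list[list[int]] | stimulus sequence IDs presented in each block, in order (IDs are 1-based) |
| `stimulus_durations` | list[float] | duration of each sequence ID, s; entry `k` is ID `k+1` |
| `use_times` | list[[float, float]] | per sequence ID, `[t_start, t_stop]` offsets from stimulus onset delimiting the analysis window; empty = full presentation |

The presentation timeline is computed from these fields: within each
block, presentations run back to back from the block's first-frame
time, each followed by `t_blank_time` of untagged gap; blocks abut in
time.  A frame belongs to the presentation whose half-open interval
`[start, end)` contains the frame onset time.

## Other artifacts

- **Shifts CSV** — columns `frame, dy_px, dx_px` (0-based frames;
  stored shift = content displacement relative to the reference).
- **RoiSet JSON** — `{"image_dims": [rows, cols], "regions": [[linear
  row-major pixel indices], ...], "labels": [...]}`.
- **ImageJ ROI** — binary `.roi` (magic `Iout`) and `.zip` containers;
  rectangle, oval, polygon and freehand types.
- **Baseline store** — one `.npz` (mean/std frames) per assignment plus
  `baseline_index.json` mapping each file to its frame range and
  channel.
- **Responses** — long CSV `(roi, stimulus, trial, measure, value)`,
  PSTH CSV `(stimulus, roi, frame_in_trial, value)`, and a JSON summary
  with the trial-average matrix.
- **Ground truth JSON** — every resolved random choice of the synthetic
  generator (orders, shifts, cell geometry/tuning, per-presentation
  ideal peak ΔF/F₀, a guaranteed cell-free black region).
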