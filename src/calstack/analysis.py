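"""Example analyses over extracted responses.

Three standard visual-cortex characterizations built directly on the
trial-averaged response matrix:

* receptive-field (RF) localization from a sparse-noise grid, smoothed
  by summing one Gaussian field per stimulus pixel weighted by its
  trial-averaged response — the Gaussian's FWHM equals the stimulus
  pixel diameter;
* direction tuning curves (mean and s.e.m. per drift direction); and
* response sparseness as skewness: a neuron's lifetime sparseness is
  the skewness of its responses over time, the population sparseness is
  the skewness across simultaneously recorded neurons at one time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RfGrid",
    "TuningCurve",
    "rf_map",
    "tuning_curve",
    "sparseness",
]

# FWHM = 2 * sqrt(2 ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RfGrid:
    """A regular g x g grid of stimulus pixels in visual degrees.

    ``overlap`` is the fractional overlap between adjacent pixels, so the
    center spacing is ``diameter * (1 - overlap)``.  ``responses`` holds
    the trial-averaged calcium response of each grid pixel, row-major.
    """

    grid_size: int
    pixel_diameter_deg: float
    overlap: float = 0.0
    responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.grid_size < 1 or self.pixel_diameter_deg <= 0:
            raise ValueError("grid_size >= 1 and pixel_diameter_deg > 0 required")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.responses is not None:
            self.responses = np.asarray(self.responses, dtype=float).ravel()
            if self.responses.size != self.grid_size**2:
                raise ValueError(
                    f"need {self.grid_size ** 2} responses, "
                    f"got {self.responses.size}"
                )

    @property
    def spacing_deg(self) -> float:
        return self.pixel_diameter_deg * (1.0 - self.overlap)

    def centers(self) -> np.ndarray:
        """(g*g, 2) pixel centers (x, y) in degrees, grid centered on 0."""
        g = self.grid_size
        axis = (np.arange(g) - (g - 1) / 2.0) * self.spacing_deg
        xx, yy = np.meshgrid(axis, axis)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class TuningCurve:
    directions_deg: np.ndarray
    mean: np.ndarray
    sem: np.ndarray


def rf_map(grid: RfGrid, resolution_deg: float = 0.25):
    """Smoothed RF estimate by summed response-weighted Gaussian fields.

    Each grid pixel contributes ``r_i * exp(-||x - c_i||^2 / (2 sigma^2))``
    with sigma set so the Gaussian FWHM equals the pixel diameter.  Returns
    ``(field, (xs, ys), center)`` where ``center`` is the (x, y) argmax of
    the field, or None (flagged) when all responses are zero.
    """
    if grid.responses is None:
        raise ValueError("grid has no responses")
    r = grid.responses
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    centers = grid.centers()
    sigma = grid.pixel_diameter_deg * _FWHM_TO_SIGMA
    pad = grid.pixel_diameter_deg
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    xs = np.arange(lo[0], hi[0] + resolution_deg / 2, resolution_deg)
    ys = np.arange(lo[1], hi[1] + resolution_deg / 2, resolution_deg)
    xx, yy = np.meshgrid(xs, ys)
    field = np.zeros_like(xx)
    for (cx, cy), ri in zip(centers, r):
        if ri == 0:
            continue
        field += ri * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
        )
    if np.all(r == 0):
        return field, (xs, ys), None
    iy, ix = np.unravel_index(np.argmax(field), field.shape)
    return field, (xs, ys), (float(xs[ix]), float(ys[iy]))


def tuning_curve(matrix, roi: int, directions_deg) -> TuningCurve:
    """Trial mean and s.e.m. per drift direction for one ROI.

    Requires exactly one stimulus per direction, given in stimulus-ID
    order (stimulus ``stim_ids[k]`` showed ``directions_deg[k]``).
    """
    directions = np.asarray(directions_deg, dtype=float)
    if np.unique(directions).size != directions.size or np.any(
        (directions < 0) | (directions >= 360)
    ):
        raise ValueError("directions must be distinct and in [0, 360)")
    resp = matrix.responses[roi]  # (n_stimuli, n_trials)
    if resp.shape[0] != directions.size:
        raise ValueError(
            f"{resp.shape[0]} stimuli but {directions.size} directions"
        )
    order = np.argsort(directions)
    mean = np.nanmean(resp, axis=1)
    n = np.sum(np.isfinite(resp), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.nanstd(resp, axis=1, ddof=1) / np.sqrt(n)
    sem = np.where(n > 1, sem, np.nan)
    return TuningCurve(directions[order], mean[order], sem[order])


def sparseness(values, axis: str = "lifetime"):
    """Response sparseness as the biased sample skewness g1.

    ``values`` is (n_neurons, n_time).  ``axis='lifetime'`` gives one
    skewness per neuron over time; ``axis='population'`` one per time
    point across neurons.  g1 = m3 / m2^(3/2) with divisor-n moments;
    entries with fewer than 3 finite values or zero variance are NaN.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        vals = vals[None, :] if axis == "lifetime" else vals[:, None]
    np_axis = 1 if axis == "lifetime" else 0
    if axis not in ("lifetime", "population"):
        raise ValueError(f"axis must be 'lifetime' or 'population', got {axis!r}")
    out = stats.skew(vals, axis=np_axis, bias=True, nan_policy="omit")
    out = np.asarray(out, dtype=float)
    n_ok = np.sum(np.isfinite(vals), axis=np_axis)
    var = np.nanvar(vals, axis=np_axis)
    out = np.where((n_ok >= 3) & (var > 0), out, np.nan)
    return float(out.reshape(-1)[0]) if out.size == 1 else out
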