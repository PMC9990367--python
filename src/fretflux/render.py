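"""Synthetic two-channel movie rendering.

Turns a simulated concentration time course into the raw unit of
analysis: a two-channel fluorescence stack with the artifacts real
acquisitions carry (photon shot noise, read noise, per-channel
bleaching, xy drift).  Cells are elliptical patches on a dark
background; each cell's per-frame ratio is the sensor readout of its
concentration, and the two channel intensities are synthesised so that
numerator/denominator equals that ratio at the cell's brightness.

In a mosaic scene (incomplete knockout recombination) wild-type cells
follow a separate control concentration series, so the whole-frame
ratio is a brightness-weighted mixture of the two genotypes — exactly
the dilution that patchy Cre expression causes in tissue.

Drift is rendered as integer-pixel circular shifts of the whole frame;
the per-frame truth offsets are recorded in the stack metadata so
registration can be validated against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .kinetics import ConcentrationSeries
from .sensors import SensorModel

__all__ = ["EllipseCell", "ScenePhantom", "NoiseModel", "MovieStack", "render_movie"]


@dataclass(frozen=True)
class EllipseCell:
    """One elliptical cell: center (row, col), semi-axes, brightness."""

    cy: float
    cx: float
    ry: float
    rx: float
    intensity: float = 100.0
    knockout: bool = False


@dataclass(frozen=True)
class ScenePhantom:
    """Static scene geometry: cells on a uniform background."""

    shape: tuple[int, int] = (256, 256)
    cells: tuple[EllipseCell, ...] = ()
    background: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        h, w = self.shape
        for c in self.cells:
            if not (0 <= c.cy - c.ry and c.cy + c.ry < h and 0 <= c.cx - c.rx and c.cx + c.rx < w):
                raise ValueError("cell region must lie inside the frame")
            if c.intensity <= self.background:
                raise ValueError("cell intensity must exceed the background")

    def cell_mask(self, cell: EllipseCell) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return ((yy - cell.cy) / cell.ry) ** 2 + ((xx - cell.cx) / cell.rx) ** 2 <= 1.0

    def foreground_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for c in self.cells:
            m |= self.cell_mask(c)
        return m

    @classmethod
    def random(
        cls,
        n_cells: int,
        *,
        shape: tuple[int, int] = (256, 256),
        mosaic_fraction: float = 0.0,
        rng: np.random.Generator | None = None,
        intensity: float = 100.0,
        background: float = 2.0,
        margin: int = 16,
        radius: tuple[float, float] = (4.0, 8.0),
    ) -> "ScenePhantom":
        """Random scene: ``n_cells`` ellipses kept away from the frame edge.

        Each cell is flagged knockout with probability ``mosaic_fraction``
        (Bernoulli per cell, the cell-level mosaicism model).
        """
        rng = np.random.default_rng() if rng is None else rng
        h, w = shape
        cells = []
        for _ in range(n_cells):
            ry, rx = rng.uniform(*radius, size=2)
            cy = rng.uniform(margin + ry, h - margin - ry)
            cx = rng.uniform(margin + rx, w - margin - rx)
            ko = bool(rng.random() < mosaic_fraction)
            scale = intensity * rng.uniform(0.8, 1.2)
            cells.append(EllipseCell(cy, cx, ry, rx, scale, ko))
        return cls(shape=shape, cells=tuple(cells), background=background)


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition artifact settings.

    ``photons_per_unit`` scales expected counts before Poisson sampling,
    so cell SNR is configurable independently of the scene brightness.
    Bleaching is a per-channel exponential decay of expected counts.
    Drift is an integer-rounded Gaussian random walk, pixels/frame.
    """

    shot_noise: bool = True
    read_noise_sd: float = 1.0           # intensity units
    bleach_rate: tuple[float, float] = (0.0, 0.0)  # (numerator, denominator), 1/s
    drift_sd: float = 0.0                # random-walk step sd, px/frame
    photons_per_unit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.drift_sd < 0 or self.photons_per_unit <= 0:
            raise ValueError("noise rates must be >= 0 and photon scale > 0")
        if any(b < 0 for b in self.bleach_rate):
            raise ValueError("bleach rates must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free, drift-free settings (rendering is then exact)."""
        return cls(shot_noise=False, read_noise_sd=0.0, bleach_rate=(0.0, 0.0), drift_sd=0.0)


@dataclass
class MovieStack:
    """Two-channel image time series.

    ``numerator`` / ``denominator`` are (T, H, W) float arrays whose
    per-pixel quotient carries the sensor ratio.  ``valid`` optionally
    marks pixels that hold real data (registration fill is invalid).
    """

    numerator: np.ndarray
    denominator: np.ndarray
    frame_rate: float
    metadata: dict[str, Any] = field(default_factory=dict)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.numerator.shape != self.denominator.shape:
            raise ValueError("channels must have the same shape")
        if self.numerator.ndim != 3:
            raise ValueError("channels must be (time, height, width)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if np.any(self.numerator < 0) or np.any(self.denominator < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.numerator.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.numerator.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def channel_sum(self) -> np.ndarray:
        return self.numerator + self.denominator


def _draw_drift(n_frames: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Integer random-walk offsets (T, 2); frame 0 is the (0, 0) reference."""
    if sd == 0:
        return np.zeros((n_frames, 2), dtype=int)
    steps = rng.normal(0.0, sd, size=(n_frames, 2))
    steps[0] = 0.0
    return np.rint(np.cumsum(steps, axis=0)).astype(int)


def render_movie(
    series: ConcentrationSeries,
    sensor: SensorModel,
    scene: ScenePhantom,
    noise: NoiseModel,
    frame_rate: float,
    *,
    duration: float | None = None,
    control_series: ConcentrationSeries | None = None,
    metadata: dict[str, Any] | None = None,
) -> MovieStack:
    """Render a two-channel movie from a concentration time course.

    Parameters
    ----------
    series : ConcentrationSeries
        Drives knockout cells (and all cells when no mosaic is present).
    sensor : SensorModel
        Maps the analyte concentration to the reported ratio; the
        analyte attribute selects lactate or glucose from the series.
    scene, noise, frame_rate
        Geometry, artifact settings, and acquisition rate (Hz).
    control_series : ConcentrationSeries, optional
        Drives wild-type (non-knockout) cells in a mosaic scene.
        Required if any cell has ``knockout=False`` while another has
        ``knockout=True``; defaults to ``series`` otherwise.

    Returns
    -------
    MovieStack
        With ``metadata['drift_truth']`` holding the rendered integer
        offsets and the scene/sensor provenance.  Identical seeds give
        bit-identical stacks.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    duration = float(series.t[-1]) if duration is None else float(duration)
    if duration > series.t[-1] + 1e-9:
        raise ValueError("series does not cover the movie duration")
    n_frames = int(np.floor(duration * frame_rate)) + 1
    t_frames = np.arange(n_frames) / frame_rate

    def conc_at(s: ConcentrationSeries) -> np.ndarray:
        track = s.lac_in if sensor.analyte == "lactate" else s.glc_in
        return np.interp(t_frames, s.t, track)

    ctrl = control_series if control_series is not None else series
    if control_series is not None and (len(ctrl.t) != len(series.t) or ctrl.t[-1] < duration - 1e-9):
        raise ValueError("control series must cover the movie duration")
    r_ko = np.asarray(sensor.forward(conc_at(series)))
    r_wt = np.asarray(sensor.forward(conc_at(ctrl)))

    # static denominator brightness and genotype regions
    den_base = np.full(scene.shape, scene.background)
    ko_region = np.zeros(scene.shape, dtype=bool)
    wt_region = np.zeros(scene.shape, dtype=bool)
    for cell in scene.cells:
        m = scene.cell_mask(cell)
        den_base[m] += cell.intensity
        (ko_region if cell.knockout else wt_region)[m] = True
    wt_region &= ~ko_region  # overlaps count as knockout

    rng = np.random.default_rng(noise.seed)
    offsets = _draw_drift(n_frames, noise.drift_sd, rng)

    num = np.empty((n_frames, *scene.shape))
    den = np.empty((n_frames, *scene.shape))
    b_num, b_den = noise.bleach_rate
    for i, t in enumerate(t_frames):
        # numerator = ratio x denominator pixelwise inside each cell,
        # so masked ratio-of-means reproduces the sensor ratio exactly
        num_i = np.where(ko_region, r_ko[i] * den_base,
                         np.where(wt_region, r_wt[i] * den_base, den_base))
        den_i = den_base
        if b_num > 0:
            num_i = num_i * np.exp(-b_num * t)
        if b_den > 0:
            den_i = den_i * np.exp(-b_den * t)
        dy, dx = offsets[i]
        if dy or dx:
            num_i = np.roll(num_i, (dy, dx), axis=(0, 1))
            den_i = np.roll(den_i, (dy, dx), axis=(0, 1))
        num[i] = num_i
        den[i] = den_i

    if noise.shot_noise:
        scale = noise.photons_per_unit
        num = rng.poisson(num * scale).astype(float) / scale
        den = rng.poisson(den * scale).astype(float) / scale
    if noise.read_noise_sd > 0:
        num = num + rng.normal(0.0, noise.read_noise_sd, num.shape)
        den = den + rng.normal(0.0, noise.read_noise_sd, den.shape)
    num = np.clip(num, 0.0, None)
    den = np.clip(den, 0.0, None)

    meta = dict(metadata or {})
    meta.update(
        drift_truth=offsets,
        sensor=sensor.analyte,
        n_cells=len(scene.cells),
        n_knockout=sum(c.knockout for c in scene.cells),
        seed=noise.seed,
    )
    return MovieStack(numerator=num, denominator=den, frame_rate=frame_rate, metadata=meta)
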