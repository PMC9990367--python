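"""Multi-level synthetic cohorts: groups -> mice -> slices -> cells.

Emulates the experimental design of a two-genotype (or multi-layer)
imaging study: each group contributes several mice, each mouse several
slices, and each slice is one two-channel movie (or directly its ratio
trace).  Biological variability enters as a lognormal multiplicative
"metabolic capacity" effect at the mouse and at the slice level, scaling
the three flux capacities (hexokinase, glucose carrier, lactate
carrier) together — slice-to-slice differences in expression, health
and imaging depth affect all fluxes jointly, which keeps flux ratios
(and with them the baseline steady state) stable while rates vary.
Mosaicism
enters at the cell level, each cell being knockout with probability
``mosaic_fraction`` so the whole-frame signal is a mixture of knockout
and wild-type kinetics — the dilution incomplete Cre recombination
causes in real tissue.

A truth table records every sampled parameter so downstream estimates
can be checked against the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    ConcentrationSeries,
    KineticParams,
    simulate_concentrations_batch,
)
from .pipeline import RatioTrace, temporal_smooth
from .protocols import Protocol
from .render import MovieStack, NoiseModel, ScenePhantom, render_movie
from .sensors import SensorModel

__all__ = ["GroupSpec", "CohortSpec", "SliceRecord", "Cohort", "generate_cohort"]

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group.

    ``param_overrides`` are applied on top of the control kinetic
    defaults (e.g. ``{"lac_prod_frac": 1.5}`` for a genotype that
    diverts more pyruvate to lactate).  ``mosaic_fraction`` is the
    probability that a cell carries the overrides; wild-type cells in
    the same slice follow the control parameters.
    """

    name: str
    n_mice: int
    slices_per_mouse: int
    param_overrides: dict[str, float] = field(default_factory=dict)
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.slices_per_mouse < 1:
            raise ValueError("need at least one mouse and one slice per mouse")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValueError("mosaic_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    between_mouse_cv: float = 0.15
    between_slice_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if self.between_mouse_cv < 0 or self.between_slice_cv < 0:
            raise ValueError("CVs must be >= 0")


@dataclass
class SliceRecord:
    """One slice: identifiers, generated data, and its true parameters."""

    stack_id: str
    group: str
    mouse: str
    slice: int
    params: KineticParams          # knockout-cell parameters
    control_params: KineticParams  # wild-type-cell parameters
    ko_weight: float               # brightness fraction of knockout cells
    movie: MovieStack | None = None
    trace: RatioTrace | None = None
    series: ConcentrationSeries | None = None
    control_series: ConcentrationSeries | None = None


@dataclass
class Cohort:
    records: list[SliceRecord]
    truth: pd.DataFrame
    protocol: Protocol
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.records)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _effect(rng: np.random.Generator, sigma: float, clip: float = 2.5) -> float:
    """Lognormal multiplicative effect, truncated at +/- ``clip`` sigma.

    Truncation keeps tail draws from producing non-physiological
    phenotypes (e.g. production exceeding export capacity).
    """
    z = float(np.clip(rng.normal(0.0, 1.0), -clip, clip))
    return float(np.exp(sigma * z))


def generate_cohort(
    spec: CohortSpec,
    protocol: Protocol,
    sensor: SensorModel,
    *,
    base_params: KineticParams | None = None,
    render: bool = False,
    frame_rate: float = 5.94,
    dt: float = 0.5,
    smoothing_window: int = 11,
    n_cells: int = 30,
    trace_noise_sd: float = 0.003,
    scene_shape: tuple[int, int] = (128, 128),
    noise: NoiseModel | None = None,
) -> Cohort:
    """Generate one movie or trace per slice, plus the truth table.

    Per slice the kinetic parameters are the group's (control defaults
    plus overrides) with all flux capacities scaled by the product of a
    lognormal mouse effect and a lognormal slice effect.  With
    ``render=True`` full two-channel
    movies are synthesised (slower); the default trace-level path maps
    the knockout/wild-type concentration mixtures straight through the
    sensor to a noisy, smoothed ratio trace — the same quantity the
    image pipeline extracts, at a fraction of the cost.

    Everything is driven by ``spec.seed``: identical specs give
    identical truth tables and data.
    """
    base = base_params or KineticParams()
    rng = np.random.default_rng(spec.seed)
    sig_m = _lognormal_sigma(spec.between_mouse_cv)
    sig_s = _lognormal_sigma(spec.between_slice_cv)

    # pass 1: sample the hierarchy and collect every parameter set to solve
    records: list[SliceRecord] = []
    truth_rows: list[dict[str, Any]] = []
    slice_seeds: list[int] = []
    sim_jobs: list[KineticParams] = []
    job_of: list[tuple[int, int | None]] = []  # (ko job index, wt job index)
    for g in spec.groups:
        ko_base = replace(base, **g.param_overrides)
        for im in range(g.n_mice):
            mouse_id = f"{g.name}-m{im:02d}"
            mouse_fac = _effect(rng, sig_m)
            for isl in range(g.slices_per_mouse):
                fac = mouse_fac * _effect(rng, sig_s)
                ko_params = ko_base.scaled(fac)
                wt_params = base.scaled(fac)

                n_ko = int(rng.binomial(n_cells, g.mosaic_fraction))
                ko_weight = n_ko / n_cells
                stack_id = f"{mouse_id}-s{isl:02d}"
                slice_seeds.append(int(rng.integers(0, 2**31 - 1)))

                ko_job = len(sim_jobs)
                sim_jobs.append(ko_params)
                wt_job = None
                if ko_weight < 1.0:
                    wt_job = len(sim_jobs)
                    sim_jobs.append(wt_params)
                job_of.append((ko_job, wt_job))

                records.append(SliceRecord(
                    stack_id=stack_id,
                    group=g.name,
                    mouse=mouse_id,
                    slice=isl,
                    params=ko_params,
                    control_params=wt_params,
                    ko_weight=ko_weight,
                ))
                row = {
                    "stack_id": stack_id, "group": g.name, "mouse": mouse_id,
                    "slice": isl, "n_cells": n_cells, "n_knockout": n_ko,
                    "ko_weight": ko_weight, "capacity_effect": fac,
                    "slice_seed": slice_seeds[-1],
                }
                for prefix, p in (("ko_", ko_params), ("wt_", wt_params)):
                    for name in ("j_hk_vmax", "glut_vmax", "mct_vmax", "lac_prod_frac",
                                 "mct4_frac", "mct_km", "k_hk_km", "glut_km"):
                        row[prefix + name] = getattr(p, name)
                truth_rows.append(row)

    # pass 2: one vectorized integration for every concentration series
    t_grid, lac, glc = simulate_concentrations_batch(sim_jobs, protocol, dt)

    def series_of(j: int) -> ConcentrationSeries:
        return ConcentrationSeries(t=t_grid, lac_in=lac[j], glc_in=glc[j])

    # pass 3: render movies or synthesize traces
    for rec, (ko_job, wt_job), slice_seed in zip(records, job_of, slice_seeds):
        series = series_of(ko_job)
        ctrl_series = series_of(wt_job) if wt_job is not None else None
        rec.series = series
        rec.control_series = ctrl_series
        g = next(gs for gs in spec.groups if gs.name == rec.group)
        n_ko = int(round(rec.ko_weight * n_cells))
        meta = {"group": rec.group, "mouse": rec.mouse, "slice": rec.slice,
                "stack_id": rec.stack_id, "protocol": protocol.name}
        if render:
            slice_rng = np.random.default_rng(slice_seed)
            scene = ScenePhantom.random(
                n_cells, shape=scene_shape, mosaic_fraction=0.0, rng=slice_rng
            )
            # impose the sampled knockout count exactly
            ko_flags = np.zeros(n_cells, dtype=bool)
            ko_flags[slice_rng.permutation(n_cells)[:n_ko]] = True
            cells = tuple(
                replace(c, knockout=bool(f)) for c, f in zip(scene.cells, ko_flags)
            )
            scene = ScenePhantom(shape=scene.shape, cells=cells, background=scene.background)
            nm = replace(noise or NoiseModel(), seed=slice_seed)
            rec.movie = render_movie(
                series, sensor, scene, nm, frame_rate,
                control_series=ctrl_series or series,
                metadata=meta,
            )
        else:
            rec.trace = _trace_from_series(
                series, ctrl_series, rec.ko_weight, sensor, frame_rate,
                smoothing_window, trace_noise_sd,
                np.random.default_rng(slice_seed),
                meta=meta,
            )
    return Cohort(records=records, truth=pd.DataFrame(truth_rows), protocol=protocol, spec=spec)


def _trace_from_series(
    series: ConcentrationSeries,
    control_series: ConcentrationSeries | None,
    ko_weight: float,
    sensor: SensorModel,
    frame_rate: float,
    window: int,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    meta: dict[str, Any],
) -> RatioTrace:
    """Whole-frame ratio trace without image rendering.

    The frame ratio of a mosaic field with equally bright cells is the
    knockout-weighted mean of the two genotype ratios; measurement
    noise is added per frame before the standard temporal smoothing.
    """
    n_frames = int(np.floor(series.t[-1] * frame_rate)) + 1
    t = np.arange(n_frames) / frame_rate

    def ratio_of(s: ConcentrationSeries) -> np.ndarray:
        track = s.lac_in if sensor.analyte == "lactate" else s.glc_in
        return np.asarray(sensor.forward(np.interp(t, s.t, track)))

    r = ratio_of(series) * ko_weight
    if ko_weight < 1.0:
        ctrl = control_series if control_series is not None else series
        r = r + (1.0 - ko_weight) * ratio_of(ctrl)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    r = temporal_smooth(r, window)
    r = np.clip(r, 1e-6, None)
    return RatioTrace(t=t, r=r, frame_rate=frame_rate, smoothing_window=window, meta=meta)
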