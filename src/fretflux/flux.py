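"""Trace-level flux readouts: basal level, amplitude, slope.

The transport-stop logic: while a carrier inhibitor blocks exchange
with the bath, the intracellular pool integrates the net metabolic
flux, so the initial post-block slope of the sensor trace is a flux
proxy and the plateau change is the accumulated amount.  Anchoring a
trace at its nominal-zero tail (oxamate depletion or aglycemia) turns
the pre-intervention level into a zero-referenced basal readout.

The public surface follows the fitted-model convention: build a
:class:`FluxModel` from a ratio trace plus its protocol, call
``fit()``, and read estimates, diagnostics and a ``summary()`` table
off the returned :class:`FluxResults`.  The underlying window
statistics are also exposed as plain functions.

Sign convention: positive slope = accumulation.  Consumption protocols
(glucose-transport block) therefore produce a negative slope and the
consumption *rate* is its magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .pipeline import RatioTrace
from .protocols import Protocol
from .sensors import SensorModel

__all__ = [
    "AnalysisConfig",
    "NormalizedTrace",
    "FluxEstimate",
    "anchor_normalize",
    "estimate_basal",
    "estimate_amplitude",
    "estimate_slope",
    "invert_to_concentration",
    "FluxModel",
    "FluxResults",
    "READOUTS_BY_PROTOCOL",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Window lengths and QC thresholds for the trace readouts.

    All windows in seconds; none are dictated by the underlying assay,
    so they are explicit, configurable choices (see docs/methods.md).
    """

    baseline_window: float = 60.0   # ends at the first intervention onset
    anchor_window: float = 30.0     # at the trace end (end_zero anchoring)
    slope_delay: float = 10.0       # dead time after onset before the fit
    slope_duration: float = 60.0    # length of the slope fit window
    plateau_window: float = 60.0    # terminal window for the amplitude
    stability_tol: float = 0.01     # max |baseline drift|, ratio/min
    saturation_guard: float = 0.95  # fraction of sensor range
    r2_floor: float = 0.5           # low-r2 flag threshold

    def __post_init__(self) -> None:
        for name in ("baseline_window", "anchor_window", "slope_delay",
                     "slope_duration", "plateau_window"):
            if getattr(self, name) < 0 or (name != "slope_delay" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class NormalizedTrace:
    """Anchored trace: dr = r - mean(r over the anchor window)."""

    t: np.ndarray
    dr: np.ndarray
    anchor_kind: str            # "end_zero" or "baseline"
    anchor_window: tuple[float, float]
    anchor_value: float         # mean raw ratio over the anchor window
    frame_rate: float
    protocol: Protocol
    meta: dict[str, Any] = field(default_factory=dict)

    def window_slice(self, t0: float, t1: float) -> np.ndarray:
        sel = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        return sel


@dataclass
class FluxEstimate:
    """One readout with its fit window and diagnostics."""

    kind: str                           # "basal" | "amplitude" | "slope"
    value: float
    units: str
    window: tuple[float, float]
    n: int
    r2: float | None = None
    fit_mid_dr: float | None = None     # fitted dr at the window midpoint
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("estimate must be finite")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("r2 must be in [0, 1]")


# ----------------------------------------------------------------------
# window statistics

def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope per s, intercept, r2) of an ordinary least-squares line."""
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), min(r2, 1.0)


def anchor_normalize(
    trace: RatioTrace,
    protocol: Protocol,
    kind: str,
    cfg: AnalysisConfig | None = None,
) -> NormalizedTrace:
    """Anchor a trace at its nominal zero or at its baseline.

    ``end_zero`` subtracts the mean ratio over the final
    ``cfg.anchor_window`` seconds (which must lie inside the protocol's
    final segment); ``baseline`` subtracts the mean over the
    ``cfg.baseline_window`` seconds preceding the first intervention.
    Anchoring is subtractive, so dr is a ratio difference that maps
    linearly to concentration in the sensor's quasi-linear range.
    """
    cfg = cfg or AnalysisConfig()
    t_end = float(trace.t[-1])
    if kind == "end_zero":
        t0, t1 = t_end - cfg.anchor_window, t_end
        last_onset = protocol.events[-1].onset
        if t0 < last_onset:
            raise ValueError("anchor window overlaps an intervention onset")
    elif kind == "baseline":
        onset = protocol.first_intervention().onset
        t0, t1 = onset - cfg.baseline_window, onset
        if t0 < 0:
            raise ValueError("baseline window starts before the trace")
    else:
        raise ValueError("kind must be 'end_zero' or 'baseline'")
    sel = (trace.t >= t0 - 1e-9) & (trace.t <= t1 + 1e-9)
    if not sel.any():
        raise ValueError("anchor window is empty")
    anchor = float(trace.r[sel].mean())
    return NormalizedTrace(
        t=trace.t,
        dr=trace.r - anchor,
        anchor_kind=kind,
        anchor_window=(t0, t1),
        anchor_value=anchor,
        frame_rate=trace.frame_rate,
        protocol=protocol,
        meta=dict(trace.meta),
    )


def estimate_basal(ntrace: NormalizedTrace, cfg: AnalysisConfig | None = None) -> FluxEstimate:
    """Basal level: mean anchored ratio over the pre-intervention window.

    Requires ``end_zero`` anchoring (the basal level is referenced to
    the nominal-zero tail).  Flags the estimate when the baseline
    drifts faster than ``cfg.stability_tol`` ratio units per minute.
    """
    cfg = cfg or AnalysisConfig()
    if ntrace.anchor_kind != "end_zero":
        raise ValueError("basal estimation requires end_zero anchoring")
    onset = ntrace.protocol.first_intervention().onset
    t0, t1 = onset - cfg.baseline_window, onset
    if t0 < -1e-9:
        raise ValueError("baseline window unavailable")
    sel = ntrace.window_slice(t0, t1)
    if sel.sum() < 2:
        raise ValueError("baseline window unavailable")
    t, y = ntrace.t[sel], ntrace.dr[sel]
    drift_per_min = _ols_line(t, y)[0] * 60.0
    flags = []
    if abs(drift_per_min) > cfg.stability_tol:
        flags.append("unstable_baseline")
    return FluxEstimate(
        kind="basal",
        value=float(y.mean()),
        units="dratio",
        window=(t0, t1),
        n=int(sel.sum()),
        flags=flags,
    )


def estimate_amplitude(
    ntrace: NormalizedTrace,
    protocol: Protocol | None = None,
    cfg: AnalysisConfig | None = None,
    *,
    sensor: SensorModel | None = None,
) -> FluxEstimate:
    """Accumulation amplitude: mean anchored ratio over the terminal plateau.

    Requires ``baseline`` anchoring.  When a sensor model is supplied,
    the estimate is flagged saturated if the raw plateau ratio exceeds
    ``cfg.saturation_guard`` of the sensor's dynamic range.
    """
    cfg = cfg or AnalysisConfig()
    protocol = protocol or ntrace.protocol
    if ntrace.anchor_kind != "baseline":
        raise ValueError("amplitude estimation requires baseline anchoring")
    protocol.first_intervention()  # must exist
    t_end = float(ntrace.t[-1])
    t0, t1 = t_end - cfg.plateau_window, t_end
    sel = ntrace.window_slice(t0, t1)
    if t0 < protocol.first_intervention().onset or sel.sum() < 2:
        raise ValueError("plateau window shorter than configured")
    flags = []
    if sensor is not None:
        raw = ntrace.dr[sel] + ntrace.anchor_value
        guard = sensor.r_min + cfg.saturation_guard * sensor.dynamic_range
        if np.any(raw > guard):
            flags.append("saturation")
    return FluxEstimate(
        kind="amplitude",
        value=float(ntrace.dr[sel].mean()),
        units="dratio",
        window=(t0, t1),
        n=int(sel.sum()),
        flags=flags,
    )


def estimate_slope(
    ntrace: NormalizedTrace,
    protocol: Protocol | None = None,
    cfg: AnalysisConfig | None = None,
    *,
    onset_index: int = 0,
) -> FluxEstimate:
    """Initial post-intervention rate: OLS slope over the fit window.

    The window is ``[onset + delay, onset + delay + duration]`` with the
    first intervention onset by default (``onset_index`` selects later
    events).  Slope is reported in ratio units per minute, positive for
    accumulation; a decaying consumption trace gives a negative slope.
    """
    cfg = cfg or AnalysisConfig()
    protocol = protocol or ntrace.protocol
    onsets = protocol.intervention_onsets
    if not onsets:
        raise ValueError("protocol has no intervention onset")
    onset = onsets[onset_index]
    t0 = onset + cfg.slope_delay
    t1 = t0 + cfg.slope_duration
    if t1 > ntrace.t[-1] + 1e-9:
        raise ValueError("fit window exceeds the trace")
    sel = ntrace.window_slice(t0, t1)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 frames in the fit window")
    t, y = ntrace.t[sel], ntrace.dr[sel]
    slope_s, intercept, r2 = _ols_line(t, y)
    flags = [] if r2 >= cfg.r2_floor else ["low_r2"]
    t_mid = 0.5 * (t0 + t1)
    return FluxEstimate(
        kind="slope",
        value=slope_s * 60.0,
        units="dratio/min",
        window=(t0, t1),
        n=int(sel.sum()),
        r2=r2,
        fit_mid_dr=float(slope_s * t_mid + intercept),
        flags=flags,
    )


def invert_to_concentration(
    est: FluxEstimate,
    anchor_value: float,
    sensor: SensorModel,
    *,
    tol: float = 1e-9,
) -> FluxEstimate:
    """Convert a ratio-unit estimate to mM (levels) or mM/min (slopes).

    Levels are differenced through the exact sensor inverse at the two
    ratio points; slopes are divided by the local sensor gain at the
    fit-window midpoint ratio.
    """
    if est.kind in ("basal", "amplitude"):
        c_hi = sensor.inverse(anchor_value + est.value, tol=tol)
        c_lo = sensor.inverse(anchor_value, tol=tol)
        value, units = c_hi - c_lo, "mM"
    elif est.kind == "slope":
        if est.fit_mid_dr is None:
            raise ValueError("slope estimate lacks a fit midpoint")
        c_mid = sensor.inverse(anchor_value + est.fit_mid_dr, tol=tol)
        g = sensor.gain(c_mid)
        if g <= 0:
            raise ValueError("sensor gain vanishes at the fit midpoint")
        value, units = est.value / g, "mM/min"
    else:
        raise ValueError(f"unknown estimate kind {est.kind!r}")
    return replace(est, value=float(value), units=units)


# ----------------------------------------------------------------------
# model / results objects

#: Which readouts each protocol supports and the anchoring each needs.
READOUTS_BY_PROTOCOL: dict[str, dict[str, str]] = {
    "trans_acceleration": {"basal": "end_zero"},
    "mct_block": {"amplitude": "baseline", "slope": "baseline"},
    "glut_block_then_aglycemia": {"basal": "end_zero", "slope": "end_zero"},
    "aglycemia_only": {"basal": "end_zero"},
}


class FluxModel:
    """Trace-level flux readout model.

    Parameters
    ----------
    trace : RatioTrace
        Processed whole-frame ratio trace.
    protocol : Protocol
        The intervention timeline the trace was acquired under; decides
        which readouts are defined and how the trace is anchored.
    config : AnalysisConfig, optional
    sensor : SensorModel, optional
        Enables the saturation guard and mM conversion.

    Examples
    --------
    >>> model = FluxModel(trace, protocol, sensor=LACONIC)   # doctest: +SKIP
    >>> res = model.fit()                                    # doctest: +SKIP
    >>> res.slope, res.r2                                    # doctest: +SKIP
    """

    def __init__(
        self,
        trace: RatioTrace,
        protocol: Protocol,
        config: AnalysisConfig | None = None,
        sensor: SensorModel | None = None,
    ) -> None:
        self.trace = trace
        self.protocol = protocol
        self.config = config or AnalysisConfig()
        self.sensor = sensor
        if protocol.name not in READOUTS_BY_PROTOCOL:
            raise ValueError(f"no readout mapping for protocol {protocol.name!r}")
        self.readouts = READOUTS_BY_PROTOCOL[protocol.name]

    @classmethod
    def from_movie(cls, movie, protocol: Protocol, *, window: int,
                   config: AnalysisConfig | None = None,
                   sensor: SensorModel | None = None, register: bool = True) -> "FluxModel":
        """Run the image pipeline and build the model from a raw stack."""
        from .pipeline import process_movie

        trace, _, _ = process_movie(movie, window=window, register=register)
        return cls(trace, protocol, config=config, sensor=sensor)

    def fit(self) -> "FluxResults":
        cfg = self.config
        estimates: dict[str, FluxEstimate] = {}
        anchors: dict[str, NormalizedTrace] = {}
        for readout, anchoring in self.readouts.items():
            if anchoring not in anchors:
                anchors[anchoring] = anchor_normalize(self.trace, self.protocol, anchoring, cfg)
            nt = anchors[anchoring]
            if readout == "basal":
                estimates["basal"] = estimate_basal(nt, cfg)
            elif readout == "amplitude":
                estimates["amplitude"] = estimate_amplitude(nt, self.protocol, cfg, sensor=self.sensor)
            elif readout == "slope":
                estimates["slope"] = estimate_slope(nt, self.protocol, cfg)
        return FluxResults(self, estimates, anchors)


class FluxResults:
    """Estimates, uncertainty diagnostics and summary for one trace."""

    def __init__(
        self,
        model: FluxModel,
        estimates: dict[str, FluxEstimate],
        anchors: dict[str, NormalizedTrace],
    ) -> None:
        self.model = model
        self.estimates = estimates
        self.anchors = anchors

    # convenient attribute access ------------------------------------
    def _value(self, kind: str) -> float | None:
        est = self.estimates.get(kind)
        return None if est is None else est.value

    @property
    def basal(self) -> float | None:
        return self._value("basal")

    @property
    def amplitude(self) -> float | None:
        return self._value("amplitude")

    @property
    def slope(self) -> float | None:
        """Signed rate, ratio/min (positive = accumulation)."""
        return self._value("slope")

    @property
    def consumption_rate(self) -> float | None:
        """Magnitude of a negative (decay) slope, ratio/min."""
        s = self.slope
        return None if s is None else abs(min(s, 0.0))

    @property
    def r2(self) -> float | None:
        est = self.estimates.get("slope")
        return None if est is None else est.r2

    @property
    def flags(self) -> list[str]:
        out: list[str] = []
        for est in self.estimates.values():
            out.extend(est.flags)
        return sorted(set(out))

    def in_mM(self) -> dict[str, FluxEstimate]:
        """All estimates converted to concentration units."""
        if self.model.sensor is None:
            raise ValueError("a SensorModel is required for mM conversion")
        out = {}
        for kind, est in self.estimates.items():
            anchoring = self.model.readouts[kind]
            anchor_value = self.anchors[anchoring].anchor_value
            out[kind] = invert_to_concentration(est, anchor_value, self.model.sensor)
        return out

    def to_row(self) -> dict[str, Any]:
        """Flat record for the per-trace results table."""
        row: dict[str, Any] = {
            "protocol": self.model.protocol.name,
            "basal_dratio": self.basal,
            "amplitude_dratio": self.amplitude,
            "slope_dratio_per_min": self.slope,
            "slope_r2": self.r2,
            "flags": ";".join(self.flags),
        }
        for key in ("group", "mouse", "slice", "stack_id"):
            if key in self.model.trace.meta:
                row[key] = self.model.trace.meta[key]
        return row

    def plot(self, ax=None):
        """Plot the anchored trace with the fit/anchor windows shaded.

        Returns the matplotlib axes (created on demand), for QC figures.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.5))
        # prefer the baseline-anchored view when present (accumulation
        # protocols), otherwise the end-anchored one
        nt = self.anchors.get("baseline") or self.anchors["end_zero"]
        ax.plot(nt.t, nt.dr, lw=0.8, color="0.2", label="trace")
        ax.axhline(0.0, color="0.6", lw=0.5)
        for onset in self.model.protocol.intervention_onsets:
            ax.axvline(onset, color="tab:red", lw=0.8, ls="--")
        colors = {"basal": "tab:blue", "amplitude": "tab:green", "slope": "tab:orange"}
        for kind, est in self.estimates.items():
            ax.axvspan(*est.window, alpha=0.15, color=colors[kind],
                       label=f"{kind} window")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(r"$\Delta$ratio")
        ax.set_title(self.model.protocol.name)
        ax.legend(fontsize=8, loc="best")
        return ax

    def summary(self) -> str:
        lines = [
            "Flux readout summary",
            "====================",
            f"protocol:     {self.model.protocol.name}",
            f"frames:       {len(self.model.trace)} @ {self.model.trace.frame_rate:g} Hz",
            f"smoothing:    {self.model.trace.smoothing_window} frames",
        ]
        for kind, est in self.estimates.items():
            extra = f", r2={est.r2:.4f}" if est.r2 is not None else ""
            flag = f"  [{', '.join(est.flags)}]" if est.flags else ""
            lines.append(
                f"{kind:<12s}{est.value: .5f} {est.units}"
                f"  (window {est.window[0]:.0f}-{est.window[1]:.0f} s, n={est.n}{extra}){flag}"
            )
        return "\n".join(lines)
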