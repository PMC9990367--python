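"""Run configuration: YAML parsing, validation, defaults, hashing.

Fail-closed parsing: unknown keys are errors so typos can't silently
fall back to defaults.  The smoothing window defaults to 11 frames for
the lactate sensor and 5 for the glucose sensor, the acquisition rate
to 5.94 Hz, and the protocol doses to the standard 20 mM oxamate /
5 uM AR-C155858 / 20 uM cytochalasin B presets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Any

import yaml

from .cohort import CohortSpec, GroupSpec
from .flux import AnalysisConfig
from .kinetics import KineticParams
from .protocols import Protocol, get_protocol
from .sensors import SensorModel, get_sensor

__all__ = ["RunConfig", "load_config", "config_hash"]

DEFAULT_FRAME_RATE = 5.94  # Hz
DEFAULT_WINDOWS = {"laconic": 11, "fliip": 5}  # smoothing frames per sensor


@dataclass
class RunConfig:
    sensor: SensorModel
    sensor_name: str
    protocol: Protocol
    smoothing_window: int
    frame_rate: float = DEFAULT_FRAME_RATE
    register: bool = True
    reference: int | str = 0
    score_floor: float = 0.3
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    base_params: KineticParams = field(default_factory=KineticParams)
    cohort: CohortSpec | None = None
    render: bool = False
    n_cells: int = 30
    trace_noise_sd: float = 0.003
    scene_shape: tuple[int, int] = (128, 128)
    outdir: Path = Path("fretflux_out")
    seed: int = 0
    posthoc: str = "dunn"
    reference_group: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.smoothing_window % 2 == 0 or self.smoothing_window < 1:
            raise ValueError(f"smoothing_window must be odd and >= 1, got {self.smoothing_window}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.posthoc not in ("dunn", "dunnett"):
            raise ValueError("posthoc must be 'dunn' or 'dunnett'")

    def hash(self) -> str:
        return config_hash(self)


def _take(section: dict[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build(mapping: dict[str, Any], cls, where: str):
    allowed = {f.name for f in dc_fields(cls)}
    _take(mapping, allowed, where)
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {where}: {exc}") from exc


def load_config(path: str | Path | None = None, data: dict[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Either ``path`` or an already-parsed ``data`` mapping.  Minimal
    configs need only ``sensor`` and ``protocol``; everything else has
    defaults.  Unknown keys anywhere are rejected with the offending
    key named.
    """
    if data is None:
        if path is None:
            raise ValueError("need a config path or mapping")
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    top_allowed = {
        "sensor", "sensor_params", "protocol", "protocol_onset", "protocol_duration",
        "smoothing_window", "frame_rate", "register", "reference", "score_floor",
        "analysis", "kinetics", "cohort", "render", "n_cells", "trace_noise_sd",
        "outdir", "seed", "posthoc", "reference_group", "log_level", "scene_shape",
    }
    _take(data, top_allowed, "config")

    sensor_name = str(data.get("sensor", "laconic")).lower()
    sensor = get_sensor(sensor_name)
    if "sensor_params" in data:
        sp = dict(data["sensor_params"])
        _take(sp, {"kd", "hill", "r_min", "r_max"}, "sensor_params")
        sensor = replace(sensor, **sp)

    protocol = get_protocol(
        str(data.get("protocol", "mct_block")),
        onset=float(data.get("protocol_onset", 120.0)),
        duration=data.get("protocol_duration"),
    )

    window = int(data.get("smoothing_window", DEFAULT_WINDOWS[sensor_name]))
    analysis = _build(dict(data.get("analysis", {})), AnalysisConfig, "analysis")
    base_params = _build(dict(data.get("kinetics", {})), KineticParams, "kinetics")

    cohort = None
    if "cohort" in data:
        c = dict(data["cohort"])
        _take(c, {"groups", "between_mouse_cv", "between_slice_cv", "seed"}, "cohort")
        groups = []
        for g in c.get("groups", []):
            g = dict(g)
            _take(g, {"name", "n_mice", "slices_per_mouse", "param_overrides", "mosaic_fraction"},
                  f"cohort group {g.get('name', '?')!r}")
            groups.append(GroupSpec(
                name=str(g["name"]),
                n_mice=int(g["n_mice"]),
                slices_per_mouse=int(g["slices_per_mouse"]),
                param_overrides=dict(g.get("param_overrides", {})),
                mosaic_fraction=float(g.get("mosaic_fraction", 1.0)),
            ))
        cohort = CohortSpec(
            groups=tuple(groups),
            between_mouse_cv=float(c.get("between_mouse_cv", 0.15)),
            between_slice_cv=float(c.get("between_slice_cv", 0.10)),
            seed=int(c.get("seed", data.get("seed", 0))),
        )

    return RunConfig(
        sensor=sensor,
        sensor_name=sensor_name,
        protocol=protocol,
        smoothing_window=window,
        frame_rate=float(data.get("frame_rate", DEFAULT_FRAME_RATE)),
        register=bool(data.get("register", True)),
        reference=data.get("reference", 0),
        score_floor=float(data.get("score_floor", 0.3)),
        analysis=analysis,
        base_params=base_params,
        cohort=cohort,
        render=bool(data.get("render", False)),
        n_cells=int(data.get("n_cells", 30)),
        trace_noise_sd=float(data.get("trace_noise_sd", 0.003)),
        scene_shape=tuple(data.get("scene_shape", (128, 128))),
        outdir=Path(data.get("outdir", "fretflux_out")),
        seed=int(data.get("seed", 0)),
        posthoc=str(data.get("posthoc", "dunn")),
        reference_group=data.get("reference_group"),
        log_level=str(data.get("log_level", "INFO")),
    )


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration, for traceability."""

    def default(o: Any) -> Any:
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if hasattr(o, "value"):
            return o.value
        return repr(o)

    blob = json.dumps(_cfg_dict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _cfg_dict(cfg: RunConfig) -> dict[str, Any]:
    # outdir and log level do not affect results, so they stay out of the hash
    skip = {"outdir", "log_level"}
    d: dict[str, Any] = {}
    for f in dc_fields(cfg):
        if f.name in skip:
            continue
        v = getattr(cfg, f.name)
        if hasattr(v, "__dataclass_fields__"):
            v = asdict(v)
        d[f.name] = v
    return d
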