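"""End-to-end drivers: simulate -> process -> compare.

Each driver is a plain function over the library; the CLI is a thin
wrapper.  A fixed seed makes the whole chain deterministic, every
output table carries the configuration hash, and a failure on one stack
is recorded as a failed row without touching the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from .cohort import generate_cohort
from .config import RunConfig
from .flux import FluxModel
from .io import read_manifest, read_movie, read_trace, write_cohort
from .pipeline import process_movie
from .protocols import get_protocol
from .stats import summarize_cohort

__all__ = ["run_simulate", "run_process", "run_compare", "run_all"]

log = logging.getLogger("fretflux")


def run_simulate(cfg: RunConfig) -> tuple[Path, Path]:
    """Generate a cohort per the config; write stacks/traces, manifest, truth.

    Returns (manifest_path, truth_path).
    """
    if cfg.cohort is None:
        raise ValueError("config has no cohort section; nothing to simulate")
    spec = replace(cfg.cohort, seed=cfg.seed if cfg.cohort.seed == 0 else cfg.cohort.seed)
    cohort = generate_cohort(
        spec,
        cfg.protocol,
        cfg.sensor,
        base_params=cfg.base_params,
        render=cfg.render,
        frame_rate=cfg.frame_rate,
        smoothing_window=cfg.smoothing_window,
        n_cells=cfg.n_cells,
        trace_noise_sd=cfg.trace_noise_sd,
        scene_shape=cfg.scene_shape,
    )
    manifest, truth = write_cohort(cohort, cfg.outdir, config_hash=cfg.hash())
    log.info("simulate: wrote %d stacks to %s", len(cohort), cfg.outdir)
    return manifest, truth


def run_process(cfg: RunConfig, manifest_path: str | Path) -> Path:
    """Process every stack in a manifest into the per-trace results table.

    One row per stack; a stack that fails any stage is recorded with
    ``status='failed'`` and the error message, and processing continues.
    """
    manifest = read_manifest(manifest_path)
    indir = Path(manifest_path).parent
    rows = []
    for rec in manifest.itertuples(index=False):
        row = {
            "stack_id": rec.stack_id,
            "group": rec.group,
            "mouse": rec.mouse,
            "slice": rec.slice,
            "protocol": rec.protocol,
            "status": "ok",
            "error": "",
            "config_hash": cfg.hash(),
        }
        try:
            protocol = get_protocol(rec.protocol)
            fpath = indir / rec.file
            if fpath.suffix == ".csv":
                trace = read_trace(
                    fpath,
                    smoothing_window=cfg.smoothing_window,
                    meta={"group": rec.group, "mouse": rec.mouse,
                          "slice": rec.slice, "stack_id": rec.stack_id},
                )
            else:
                movie = read_movie(fpath)
                movie.metadata.update(group=rec.group, mouse=rec.mouse,
                                      slice=rec.slice, stack_id=rec.stack_id)
                trace, path, mask = process_movie(
                    movie, window=cfg.smoothing_window,
                    register=cfg.register, reference=cfg.reference,
                )
                row["mask_fraction"] = mask.fraction
                if path is not None:
                    row["max_abs_offset_px"] = path.max_abs_offset
                    row["min_registration_score"] = float(path.scores.min())
            res = FluxModel(trace, protocol, config=cfg.analysis, sensor=cfg.sensor).fit()
            row.update(res.to_row())
            if res.flags:
                log.warning("process: %s flagged: %s", rec.stack_id, res.flags)
        except Exception as exc:  # crash isolation: one bad stack, one failed row
            row["status"] = "failed"
            row["error"] = str(exc)
            log.error("process: %s failed: %s", rec.stack_id, exc)
        rows.append(row)
    out = pd.DataFrame(rows)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    results_path = cfg.outdir / "results.csv"
    out.to_csv(results_path, index=False)
    log.info("process: %d/%d stacks ok", int((out["status"] == "ok").sum()), len(out))
    return results_path


def run_compare(cfg: RunConfig, results_path: str | Path) -> tuple[Path, Path, Path]:
    """Group-level comparisons of a results table.

    Returns (summary_csv, comparisons_csv, report_json).
    """
    results = pd.read_csv(results_path)
    if len(results) == 0:
        raise ValueError("empty results table")
    if "config_hash" in results.columns:
        hashes = set(results["config_hash"].dropna().astype(str))
        if len(hashes) > 1:
            raise ValueError(f"results table mixes configuration hashes: {sorted(hashes)}")
    ok = results[results.get("status", "ok") == "ok"] if "status" in results.columns else results
    if ok["group"].nunique() < 2:
        raise ValueError("need at least two groups to compare")
    summary, comparisons = summarize_cohort(
        ok,
        reference=cfg.reference_group,
        posthoc=cfg.posthoc,
    )
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    s_path = cfg.outdir / "summary.csv"
    c_path = cfg.outdir / "comparisons.csv"
    summary.to_csv(s_path, index=False)
    comparisons.to_csv(c_path, index=False)
    report = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_stacks": int(len(results)),
        "n_failed": int((results.get("status", pd.Series(dtype=str)) == "failed").sum()),
        "groups": sorted(ok["group"].unique().tolist()),
        "comparisons": comparisons.to_dict(orient="records"),
    }
    r_path = cfg.outdir / "report.json"
    r_path.write_text(json.dumps(report, indent=1, default=str))
    log.info("compare: %d comparison rows", len(comparisons))
    return s_path, c_path, r_path


def run_all(cfg: RunConfig) -> Path:
    """simulate -> process -> compare; returns the report path."""
    manifest, _ = run_simulate(cfg)
    results = run_process(cfg, manifest)
    _, _, report = run_compare(cfg, results)
    return report
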