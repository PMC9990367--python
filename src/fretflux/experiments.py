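"""Canned study designs and cohort-level fitting helpers.

These are the simulated counterparts of the imaging study designs the
package analyses: a two-genotype lactate-production comparison (control
vs a knockout that diverts more pyruvate to lactate and upregulates its
lactate carrier), matched null cohorts for calibration, and a
three-population glucose comparison (photoreceptor-like cells with high
hexokinase and glucose-carrier capacity versus inner-retina-like
cells).  Tests and the reproduction script both build on them so the
study conditions are defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, GroupSpec, generate_cohort
from .flux import AnalysisConfig, FluxModel
from .kinetics import KineticParams
from .protocols import get_protocol
from .sensors import FLIIP, LACONIC, SensorModel

__all__ = [
    "KNOCKOUT_OVERRIDES",
    "INNER_RETINA_OVERRIDES",
    "knockout_cohort_spec",
    "null_cohort_spec",
    "layered_cohort_spec",
    "fit_cohort",
    "group_medians",
]

#: Knockout genotype: more pyruvate diverted to lactate, with matching
#: upregulated lactate transport capacity (so basal lactate is unchanged
#: while the production rate rises).
KNOCKOUT_OVERRIDES: dict[str, float] = {"lac_prod_frac": 1.5, "mct_vmax": 0.075}

#: Inner-retina-like cells: one third the hexokinase capacity of
#: photoreceptors and lower glucose-carrier capacity.
INNER_RETINA_OVERRIDES: dict[str, float] = {"j_hk_vmax": 0.01 / 3.0, "glut_vmax": 0.01}


def knockout_cohort_spec(
    seed: int,
    *,
    n_mice: int = 10,
    slices_per_mouse: int = 2,
    production_multiplier: float = 1.5,
    mosaic_fraction: float = 1.0,
) -> CohortSpec:
    """Control vs knockout design for the lactate-production comparison.

    The knockout multiplies both the lactate yield per glucose and the
    lactate export capacity by ``production_multiplier`` (capped at the
    admissible yield of 2 lactate per glucose).
    """
    base = KineticParams()
    overrides = {
        "lac_prod_frac": min(2.0, base.lac_prod_frac * production_multiplier),
        "mct_vmax": base.mct_vmax * production_multiplier,
    }
    return CohortSpec(
        groups=(
            GroupSpec("ctrl", n_mice, slices_per_mouse),
            GroupSpec("knockout", n_mice, slices_per_mouse, overrides, mosaic_fraction),
        ),
        seed=seed,
    )


def null_cohort_spec(seed: int, *, n_per_group: int = 8) -> CohortSpec:
    """Two groups with identical generative parameters (type-I calibration).

    One slice per mouse keeps the slice-level observations independent,
    and eight per group keeps the Mann-Whitney test on its exact
    enumeration path.
    """
    return CohortSpec(
        groups=(
            GroupSpec("ctrl", n_per_group, 1),
            GroupSpec("sham", n_per_group, 1),
        ),
        seed=seed,
    )


def layered_cohort_spec(seed: int, *, n_per_group: int = 15) -> CohortSpec:
    """Photoreceptor-like vs two inner-retina-like populations (glucose)."""
    return CohortSpec(
        groups=(
            GroupSpec("PR", n_per_group, 1),
            GroupSpec("INL", n_per_group, 1, dict(INNER_RETINA_OVERRIDES)),
            GroupSpec("GCL", n_per_group, 1, dict(INNER_RETINA_OVERRIDES)),
        ),
        seed=seed,
    )


def fit_cohort(
    cohort: Cohort,
    sensor: SensorModel,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Fit the flux model to every trace in a cohort.

    Returns the per-trace results table (one row per slice, the same
    schema the processing driver writes).
    """
    rows = []
    for rec in cohort.records:
        if rec.trace is None:
            raise ValueError(f"record {rec.stack_id} has no trace; run the image pipeline first")
        res = FluxModel(rec.trace, cohort.protocol, config=config, sensor=sensor).fit()
        row = res.to_row()
        row["consumption_rate_dratio_per_min"] = res.consumption_rate
        rows.append(row)
    return pd.DataFrame(rows)


def group_medians(results: pd.DataFrame, readout: str) -> dict[str, float]:
    """Median of a readout per group (QC-flagged rows excluded)."""
    ok = results[results["flags"].fillna("").astype(str).str.len() == 0]
    return {g: float(np.median(v)) for g, v in ok.groupby("group")[readout]}


# ----------------------------------------------------------------------
# replicate-level experiments (Monte-Carlo building blocks)

def directional_replicate(seed: int, *, production_multiplier: float = 1.5,
                          mosaic_fraction: float = 1.0,
                          n_mice: int = 10, slices_per_mouse: int = 2) -> dict[str, float]:
    """One control-vs-knockout accumulation experiment.

    Returns the knockout-minus-control difference of group median slope
    and amplitude (ratio units) under the lactate-accumulation protocol.
    """
    spec = knockout_cohort_spec(
        seed, n_mice=n_mice, slices_per_mouse=slices_per_mouse,
        production_multiplier=production_multiplier, mosaic_fraction=mosaic_fraction,
    )
    cohort = generate_cohort(spec, get_protocol("mct_block"), LACONIC)
    results = fit_cohort(cohort, LACONIC)
    slopes = group_medians(results, "slope_dratio_per_min")
    amps = group_medians(results, "amplitude_dratio")
    return {
        "slope_diff": slopes["knockout"] - slopes["ctrl"],
        "amplitude_diff": amps["knockout"] - amps["ctrl"],
    }


def null_replicate(seed: int) -> dict[str, float]:
    """One null experiment per readout family; returns Mann-Whitney p-values.

    Both groups share identical generative parameters, so each p-value
    is a draw from the test's null distribution: basal lactate under
    the trans-acceleration protocol, and basal glucose plus consumption
    rate under the glucose-transport-block protocol.
    """
    from .stats import GroupSample, mann_whitney_u

    out: dict[str, float] = {}
    spec = null_cohort_spec(seed)
    cohort = generate_cohort(spec, get_protocol("trans_acceleration"), LACONIC)
    res = fit_cohort(cohort, LACONIC)
    by_group = {g: tuple(v) for g, v in res.groupby("group")["basal_dratio"]}
    out["basal_lactate"] = mann_whitney_u(
        GroupSample("ctrl", by_group["ctrl"]), GroupSample("sham", by_group["sham"])
    ).p

    spec_g = null_cohort_spec((seed + 2**20) % (2**31 - 1))
    cohort_g = generate_cohort(
        spec_g, get_protocol("glut_block_then_aglycemia"), FLIIP, smoothing_window=5
    )
    res_g = fit_cohort(cohort_g, FLIIP)
    for readout, key in (("basal_dratio", "basal_glucose"),
                         ("consumption_rate_dratio_per_min", "glucose_consumption")):
        by_group = {g: tuple(v) for g, v in res_g.groupby("group")[readout]}
        out[key] = mann_whitney_u(
            GroupSample("ctrl", by_group["ctrl"]), GroupSample("sham", by_group["sham"])
        ).p
    return out


def layered_replicate(seed: int, *, alpha: float = 0.05) -> bool:
    """One three-population glucose experiment.

    True when Kruskal-Wallis plus many-to-one post hoc comparisons flag
    the photoreceptor-like group's consumption rate against both
    inner-retina-like groups at the given level.
    """
    from .stats import GroupSample, kruskal_wallis, posthoc_vs_reference

    cohort = generate_cohort(
        layered_cohort_spec(seed), get_protocol("glut_block_then_aglycemia"),
        FLIIP, smoothing_window=5,
    )
    res = fit_cohort(cohort, FLIIP)
    samples = [
        GroupSample(g, tuple(v))
        for g, v in res.groupby("group")["consumption_rate_dratio_per_min"]
    ]
    if kruskal_wallis(samples).p >= alpha:
        return False
    posthoc = posthoc_vs_reference(samples, "PR")
    return all(r.adjusted_p < alpha for r in posthoc)


def mct4_escape_slopes(fractions=(0.0, 0.2, 0.4)) -> list[float]:
    """Noise-free post-block slope at each blocker-insensitive fraction."""
    from .cohort import _trace_from_series
    from .kinetics import simulate_concentrations

    protocol = get_protocol("mct_block")
    slopes = []
    for frac in fractions:
        params = replace(KineticParams(), mct4_frac=frac)
        series = simulate_concentrations(params, protocol, dt=0.5)
        trace = _trace_from_series(
            series, None, 1.0, LACONIC, 5.94, 11, 0.0,
            np.random.default_rng(0), meta={},
        )
        res = FluxModel(trace, protocol, sensor=LACONIC).fit()
        slopes.append(float(res.slope))
    return slopes


def mosaic_dilution_curve(
    fractions=(1.0, 0.7, 0.4), *, n_replicates: int = 15, seed: int = 0
) -> list[float]:
    """Mean knockout-minus-control median slope at each mosaic fraction.

    The same replicate seeds are reused across fractions (paired
    design), isolating the dilution effect from sampling noise.
    """
    curve = []
    for frac in fractions:
        diffs = [
            directional_replicate(seed + rep, mosaic_fraction=frac)["slope_diff"]
            for rep in range(n_replicates)
        ]
        curve.append(float(np.mean(diffs)))
    return curve
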