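"""Nonparametric group comparisons on per-trace readouts.

The observational unit is the slice (one trace per retinal slice or
flatmount field); mice contribute several slices, so an optional
mouse-aggregated mode (median per mouse) is provided for conservative
inference.  Two groups are compared by the Mann-Whitney U test (exact
enumeration for small tie-free samples, normal approximation with tie
and continuity corrections otherwise); three or more groups by
Kruskal-Wallis followed by many-to-one post hoc comparisons against a
reference group — Dunn-style rank z tests with Bonferroni adjustment by
default, or the parametric Dunnett procedure as an explicit
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "posthoc_vs_reference",
    "summarize_cohort",
    "significance_stars",
]


@dataclass(frozen=True)
class GroupSample:
    """Per-group slice-level readout values (with optional mouse ids)."""

    name: str
    values: tuple[float, ...]
    mouse_ids: tuple[Any, ...] | None = None

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 1:
            raise ValueError(f"group {self.name!r} is empty")
        if not all(np.isfinite(vals)):
            raise ValueError(f"group {self.name!r} has non-finite values")
        if self.mouse_ids is not None and len(self.mouse_ids) != len(vals):
            raise ValueError("mouse_ids must parallel values")

    def __len__(self) -> int:
        return len(self.values)

    def by_mouse(self) -> "GroupSample":
        """Collapse to one median value per mouse."""
        if self.mouse_ids is None:
            raise ValueError("no mouse ids recorded")
        df = pd.DataFrame({"m": self.mouse_ids, "v": self.values})
        agg = df.groupby("m")["v"].median()
        return GroupSample(self.name, tuple(agg.values), tuple(agg.index))


@dataclass(frozen=True)
class ComparisonResult:
    statistic_name: str
    statistic: float
    p: float
    n: tuple[int, ...]
    method: str
    groups: tuple[str, ...]
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def significance_stars(p: float) -> str:
    """Figure-convention stars: thresholds 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, thr in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= thr:
            return stars
    return "ns"


def _has_ties(a: Sequence[float], b: Sequence[float]) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(a: GroupSample, b: GroupSample) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Reports ``U = min(U_a, U_b)``.  The p-value is exact (full
    enumeration of rank assignments) when both groups have n <= 8 and
    the pooled sample is tie-free; otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    x, y = np.asarray(a.values), np.asarray(b.values)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied data: no evidence against the null
        u, p, method = len(x) * len(y) / 2.0, 1.0, "degenerate ties"
    else:
        exact = len(x) <= 8 and len(y) <= 8 and not _has_ties(x, y)
        method = "exact" if exact else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
        u = min(float(res.statistic), len(x) * len(y) - float(res.statistic))
        p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        statistic_name="U",
        statistic=u,
        p=p,
        n=(len(x), len(y)),
        method=f"mann-whitney ({method})",
        groups=(a.name, b.name),
    )


def kruskal_wallis(groups: Sequence[GroupSample]) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square reference)."""
    if len(groups) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; use mann_whitney_u for two")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    pooled = np.concatenate([g.values for g in groups])
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # fully tied data carry no evidence
    else:
        h, p = sps.kruskal(*[g.values for g in groups])
    return ComparisonResult(
        statistic_name="H",
        statistic=float(h),
        p=float(p),
        n=tuple(len(g) for g in groups),
        method="kruskal-wallis",
        groups=tuple(g.name for g in groups),
    )


def _dunn_vs_reference(groups: Sequence[GroupSample], ref: GroupSample) -> list[ComparisonResult]:
    """Dunn-style many-to-one rank z tests, Bonferroni over k-1 comparisons."""
    all_vals = np.concatenate([g.values for g in groups])
    n_total = len(all_vals)
    ranks = sps.rankdata(all_vals)
    # tie correction to the rank variance
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks: dict[str, float] = {}
    i = 0
    for g in groups:
        mean_ranks[g.name] = float(ranks[i : i + len(g)].mean())
        i += len(g)

    k = len(groups)
    out = []
    for g in groups:
        if g.name == ref.name:
            continue
        se = np.sqrt(var_unit * (1.0 / len(g) + 1.0 / len(ref)))
        z = (mean_ranks[g.name] - mean_ranks[ref.name]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(
            ComparisonResult(
                statistic_name="z",
                statistic=float(z),
                p=float(min(p, 1.0)),
                n=(len(g), len(ref)),
                method="dunn many-to-one",
                groups=(g.name, ref.name),
                adjusted_p=float(min(p * (k - 1), 1.0)),
            )
        )
    return out


def _dunnett_vs_reference(groups: Sequence[GroupSample], ref: GroupSample) -> list[ComparisonResult]:
    """Parametric Dunnett many-to-one procedure (alternative path)."""
    others = [g for g in groups if g.name != ref.name]
    res = sps.dunnett(*[np.asarray(g.values) for g in others], control=np.asarray(ref.values))
    out = []
    for g, stat, p in zip(others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
        out.append(
            ComparisonResult(
                statistic_name="t",
                statistic=float(stat),
                p=float(p),
                n=(len(g), len(ref)),
                method="dunnett",
                groups=(g.name, ref.name),
                adjusted_p=float(p),  # Dunnett p is already multiplicity-adjusted
            )
        )
    return out


def posthoc_vs_reference(
    groups: Sequence[GroupSample],
    reference: str,
    *,
    method: str = "dunn",
) -> list[ComparisonResult]:
    """Many-to-one post hoc comparisons after Kruskal-Wallis.

    ``method='dunn'`` (default) uses pooled-rank z statistics with
    Bonferroni adjustment over the k-1 comparisons; ``method='dunnett'``
    runs the parametric Dunnett procedure instead.
    """
    kruskal_wallis(groups)  # validates applicability
    by_name = {g.name: g for g in groups}
    if reference not in by_name:
        raise ValueError(f"reference group {reference!r} not present")
    ref = by_name[reference]
    if method == "dunn":
        return _dunn_vs_reference(groups, ref)
    if method == "dunnett":
        return _dunnett_vs_reference(groups, ref)
    raise ValueError("method must be 'dunn' or 'dunnett'")


# ----------------------------------------------------------------------
# cohort summary

READOUT_COLUMNS = ("basal_dratio", "amplitude_dratio", "slope_dratio_per_min")


def summarize_cohort(
    results: pd.DataFrame,
    *,
    reference: str | None = None,
    readouts: Iterable[str] = READOUT_COLUMNS,
    exclude_flagged: bool = True,
    unit: str = "slice",
    posthoc: str = "dunn",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary and statistical comparisons of a results table.

    Parameters
    ----------
    results : DataFrame
        Per-trace table with ``group`` (and ideally ``mouse``) columns,
        readout columns, and a ``flags`` column.
    reference : str, optional
        Reference group for many-to-one post hoc tests (>= 3 groups);
        defaults to the first group encountered.
    exclude_flagged : bool
        Drop QC-flagged traces from the tests (they stay in the per-
        trace table upstream); excluded counts are reported.
    unit : str
        ``"slice"`` (default) or ``"mouse"`` (median per mouse first).

    Returns
    -------
    (summary, comparisons) : DataFrames
    """
    if "group" not in results.columns:
        raise ValueError("results table needs a 'group' column")
    group_names = list(pd.unique(results["group"]))
    if reference is not None and reference not in group_names:
        raise ValueError(f"unknown group {reference!r} in design")

    flags = results.get("flags")
    flagged = (
        flags.fillna("").astype(str).str.len() > 0 if flags is not None
        else pd.Series(False, index=results.index)
    )
    eligible = results[~flagged] if exclude_flagged else results

    summary_rows = []
    comparison_rows = []
    for readout in readouts:
        if readout not in results.columns:
            continue
        if results[readout].isna().all():
            continue  # readout not defined for this protocol
        sub = eligible.dropna(subset=[readout])
        samples = []
        for name in group_names:
            g = sub[sub["group"] == name]
            n_excluded = int(((results["group"] == name) & flagged).sum())
            vals = g[readout].to_numpy(dtype=float)
            n_mice = g["mouse"].nunique() if "mouse" in g.columns else np.nan
            summary_rows.append(
                {
                    "readout": readout,
                    "group": name,
                    "n_slices": len(vals),
                    "n_mice": n_mice,
                    "n_excluded": n_excluded,
                    "median": np.median(vals) if len(vals) else np.nan,
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
            if len(vals):
                mouse_ids = tuple(g["mouse"]) if "mouse" in g.columns else None
                samples.append(GroupSample(name, tuple(vals), mouse_ids))
        if unit == "mouse":
            samples = [s.by_mouse() for s in samples if s.mouse_ids is not None]
        if len(samples) < 2 or any(len(s) < 1 for s in samples):
            comparison_rows.append(
                {"readout": readout, "group_a": None, "group_b": None,
                 "statistic": np.nan, "p": np.nan, "adjusted_p": np.nan,
                 "stars": "", "note": "no eligible traces"}
            )
            continue
        if len(samples) == 2:
            res = mann_whitney_u(samples[0], samples[1])
            comparison_rows.append(_comparison_row(readout, res))
        else:
            omni = kruskal_wallis(samples)
            comparison_rows.append(_comparison_row(readout, omni))
            ref = reference or samples[0].name
            for res in posthoc_vs_reference(samples, ref, method=posthoc):
                comparison_rows.append(_comparison_row(readout, res))
    return pd.DataFrame(summary_rows), pd.DataFrame(comparison_rows)


def _comparison_row(readout: str, res: ComparisonResult) -> dict[str, Any]:
    p_eff = res.adjusted_p if res.adjusted_p is not None else res.p
    return {
        "readout": readout,
        "group_a": res.groups[0],
        "group_b": res.groups[1] if len(res.groups) == 2 else "all",
        "statistic": res.statistic,
        "statistic_name": res.statistic_name,
        "p": res.p,
        "adjusted_p": res.adjusted_p,
        "stars": significance_stars(p_eff),
        "note": res.method,
    }
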