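"""Nested-replicate (SuperPlot) aggregation and hypothesis tests.

Per-cell metrics are technical replicates nested in biological replicates
(batches of cells).  Following the SuperPlot convention, inference runs on
replicate means by default — never on pooled cells, which would
pseudoreplicate.  Two tests are provided: Dunnett's many-to-one comparison
against a control (multiplicity-adjusted via the multivariate-t reference
distribution) and the two-sided Mann–Whitney U test (exact enumeration for
small tie-free samples, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SuperPlotTable",
    "superplot_summarize",
    "dunnett_test",
    "mannwhitney_u",
]

REQUIRED_COLUMNS = ("value", "cell_id", "replicate", "condition")

# Fixed stream for the quasi-Monte Carlo evaluation of the multivariate-t
# CDF inside Dunnett's test, so repeated calls give reproducible p-values.
_DUNNETT_RNG_SEED = 715


@dataclass
class SuperPlotTable:
    """Raw per-cell rows plus the per-replicate means table."""

    rows: pd.DataFrame  # columns: value, cell_id, replicate, condition
    replicate_means: pd.DataFrame  # columns: condition, replicate, mean, n_cells

    def means_by_condition(self) -> dict[str, np.ndarray]:
        return {
            str(cond): grp["mean"].to_numpy(dtype=float)
            for cond, grp in self.replicate_means.groupby("condition", sort=True)
        }


def superplot_summarize(rows: pd.DataFrame) -> SuperPlotTable:
    """Aggregate per-cell values into per-replicate means and counts.

    ``rows`` needs columns ``value``, ``cell_id``, ``replicate``,
    ``condition``; each row is one cell.  The summary is invariant to row
    order.  Raises on an empty table or missing columns.
    """
    rows = pd.DataFrame(rows)
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if rows.empty:
        raise ValueError("no rows to summarise")
    means = (
        rows.groupby(["condition", "replicate"], sort=True)["value"]
        .agg(mean="mean", n_cells="size")
        .reset_index()
    )
    return SuperPlotTable(rows=rows.reset_index(drop=True), replicate_means=means)


def _groups_from(data: SuperPlotTable | dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if isinstance(data, SuperPlotTable):
        return data.means_by_condition()
    return {str(k): np.asarray(v, dtype=float) for k, v in data.items()}


def dunnett_test(
    data: SuperPlotTable | dict[str, np.ndarray],
    control: str,
    *,
    level: str = "replicate",
) -> pd.DataFrame:
    """Dunnett's many-to-one comparison of treatments against a control.

    ``data`` is either a :class:`SuperPlotTable` (replicate means are used)
    or a mapping of condition → values.  Returns a DataFrame indexed by
    treatment with columns ``statistic`` and ``p_adjusted`` (two-sided,
    multiplicity-adjusted over all treatments via the multivariate-t
    distribution with pooled variance).  Every group needs at least two
    values (otherwise there is no within-group variance and a ``ValueError``
    is raised).

    ``level='cell'`` pools individual cells instead of replicate means; this
    pseudoreplicates and is only offered for comparison (a warning is
    emitted).
    """
    if level not in ("replicate", "cell"):
        raise ValueError("level must be 'replicate' or 'cell'")
    if level == "cell":
        if not isinstance(data, SuperPlotTable):
            raise ValueError("level='cell' requires a SuperPlotTable")
        warnings.warn(
            "Dunnett on pooled cells pseudoreplicates; prefer replicate means",
            stacklevel=2,
        )
        groups = {
            str(cond): grp["value"].to_numpy(dtype=float)
            for cond, grp in data.rows.groupby("condition", sort=True)
        }
    else:
        groups = _groups_from(data)
    if control not in groups:
        raise ValueError(f"control condition {control!r} not present")
    for name, values in groups.items():
        if values.size < 2:
            raise ValueError(
                f"group {name!r} has fewer than 2 values; "
                "no within-group variance available"
            )
    treatments = sorted(k for k in groups if k != control)
    if not treatments:
        raise ValueError("no treatment groups to compare against the control")
    res = sps.dunnett(
        *[groups[t] for t in treatments],
        control=groups[control],
        alternative="two-sided",
        rng=np.random.default_rng(_DUNNETT_RNG_SEED),
    )
    return pd.DataFrame(
        {"statistic": res.statistic, "p_adjusted": res.pvalue}, index=treatments
    )


def mannwhitney_u(
    x: np.ndarray, y: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns ``(U_x, p)``.

    ``U_x`` is the rank-sum statistic for ``x`` (``U_x + U_y = n_x · n_y``).
    ``mode='exact'`` enumerates the permutation null (valid without ties);
    ``mode='normal_approx'`` uses the tie-corrected normal approximation with
    continuity correction; ``mode='auto'`` picks exact when
    ``n_x + n_y ≤ 12`` and there are no ties, the approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        combined = np.concatenate([x, y])
        has_ties = np.unique(combined).size < combined.size
        method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'normal_approx'")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
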