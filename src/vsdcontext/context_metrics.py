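"""Characteristic activation types and contextual facilitation metrics.

From the fitted dual-Gaussian parameters of the 8 stimulus conditions, four
characteristic activation types are derived per (location, movie) comparison
cell — 4 cells per experiment:

* direct     — the spot's own fit when its own patch was shown alone;
* indirect   — the spot's fit when only the *distant* patch was shown;
* coherent   — the spot's fit in the same-movie pair condition;
* incoherent — the spot's fit in the mixed-movie pair condition.

The amplitude metrics, all in percent of the direct peak:

* total facilitation   = 100 (A_coh - A_dir) / A_dir
* superadditive        = 100 (A_coh - (A_dir + A_ind)) / A_dir
* linear               = total - superadditive = 100 A_ind / A_dir
* specificity          = 100 (A_coh - A_incoh) / A_incoh
* incoherent vs direct = 100 (A_incoh - A_dir) / A_dir

Spread metrics compare sigma_x, sigma_y and the joint spread (geometric mean
of the two) between coherent-vs-direct and coherent-vs-incoherent fits.
Per-cell percentages are computed first and then averaged across cells, so
the paired tests act on the same per-cell values as the point estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile_fit import Gaussian2D, TwoSpotFit
from .stats import DEFAULT_ALPHA, DEFAULT_N_BOOT, EstimateWithCI, estimate

ACTIVATION_TYPES = ("direct", "indirect", "coherent", "incoherent")

#: condition providing each activation type per (location, movie) cell.
#: (own single, other single, coherent pair, incoherent pair)
_CELL_CONDITIONS: dict[tuple[str, int], dict[str, str]] = {
    ("A", 1): {"direct": "A1", "indirect": "B1", "coherent": "A1B1", "incoherent": "A1B2"},
    ("A", 2): {"direct": "A2", "indirect": "B2", "coherent": "A2B2", "incoherent": "A2B1"},
    ("B", 1): {"direct": "B1", "indirect": "A1", "coherent": "A1B1", "incoherent": "A2B1"},
    ("B", 2): {"direct": "B2", "indirect": "A2", "coherent": "A2B2", "incoherent": "A1B2"},
}


class IncompleteConditionsError(ValueError):
    """Some stimulus conditions required for the characteristic set are missing."""


@dataclass
class CharacteristicSet:
    """Fitted Gaussians for the four activation types per (location, movie).

    ``cells[(location, movie)][type]`` is the spot's :class:`Gaussian2D`; all
    four entries of a cell come from fits sharing that location's constraint
    box, so their parameters are directly comparable.
    """

    cells: dict[tuple[str, int], dict[str, Gaussian2D]]
    converged: dict[tuple[str, int], dict[str, bool]] = field(default_factory=dict)

    def cell_keys(self) -> list[tuple[str, int]]:
        return sorted(self.cells)


@dataclass
class ContextMetrics:
    """Aggregated contextual metrics with bootstrap CIs and paired p-values."""

    estimates: dict[str, EstimateWithCI]
    per_cell: pd.DataFrame
    n_excluded: int = 0
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            rows.append({
                "metric": name, "estimate": est.point,
                "ci_lo": est.ci_lo, "ci_hi": est.ci_hi, "n": est.n,
                "p_signrank": est.p_signrank, "p_signtest": est.p_signtest,
                "p_ttest": est.p_ttest,
            })
        return pd.DataFrame(rows, columns=["metric", "estimate", "ci_lo", "ci_hi", "n",
                                           "p_signrank", "p_signtest", "p_ttest"])


def build_characteristics(fits: dict[str, TwoSpotFit]) -> CharacteristicSet:
    """Map per-condition fits to the 4 x (location, movie) characteristic cells."""
    needed = sorted({cond for conds in _CELL_CONDITIONS.values() for cond in conds.values()})
    missing = [c for c in needed if c not in fits]
    if missing:
        raise IncompleteConditionsError(f"missing condition fits: {missing}")
    cells: dict[tuple[str, int], dict[str, Gaussian2D]] = {}
    converged: dict[tuple[str, int], dict[str, bool]] = {}
    for cell, mapping in _CELL_CONDITIONS.items():
        loc = cell[0]
        cells[cell] = {typ: fits[cond].spot(loc) for typ, cond in mapping.items()}
        converged[cell] = {typ: fits[cond].converged for typ, cond in mapping.items()}
    return CharacteristicSet(cells=cells, converged=converged)


def normalize_by_direct(cs: CharacteristicSet) -> pd.DataFrame:
    """Peak and spread parameters of each type, normalized by the direct fit.

    Returns a long table with one row per (location, movie, type) holding
    A, sigma_x, sigma_y and joint spread as ratios to the direct entry (the
    direct row is exactly 1), plus per-parameter medians across the cells.
    Cells with nonpositive direct amplitude are excluded with a warning.
    """
    rows = []
    for (loc, movie), types in cs.cells.items():
        direct = types["direct"]
        if direct.A <= 0:
            warnings.warn(f"cell ({loc}, movie {movie}): direct amplitude <= 0, excluded")
            continue
        for typ in ACTIVATION_TYPES:
            g = types[typ]
            rows.append({
                "location": loc, "movie": movie, "type": typ,
                "A": g.A / direct.A,
                "sigma_x": g.sigma_x / direct.sigma_x,
                "sigma_y": g.sigma_y / direct.sigma_y,
                "joint_spread": g.joint_spread / direct.joint_spread,
            })
    frame = pd.DataFrame(rows)
    if not frame.empty:
        medians = frame.groupby("type")[["A", "sigma_x", "sigma_y", "joint_spread"]].median()
        frame = frame.merge(medians, on="type", suffixes=("", "_median"))
    return frame


def percent_change(x_ref: float, x_new: float) -> float:
    """Percent change of ``x_new`` relative to ``x_ref``: 100 (new - ref) / ref."""
    if x_ref <= 0:
        raise ValueError(f"percent change undefined for nonpositive reference {x_ref}")
    return 100.0 * (x_new - x_ref) / x_ref


def _usable_cells(characteristic_sets) -> tuple[list[dict[str, Gaussian2D]], int]:
    """Pool cells across experiments, dropping non-usable ones pairwise."""
    cells, excluded = [], 0
    for cs in characteristic_sets:
        for key, types in cs.cells.items():
            direct_ok = types["direct"].A > 0
            conv = cs.converged.get(key, {}).get("direct", True)
            if direct_ok and conv:
                cells.append(types)
            else:
                excluded += 1
                warnings.warn(f"cell {key}: direct fit unusable (A<=0 or not converged), excluded")
    return cells, excluded


def facilitation_metrics(
    characteristic_sets,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
) -> ContextMetrics:
    """Amplitude metrics pooled across experiments' comparison cells.

    ``characteristic_sets`` is an iterable of :class:`CharacteristicSet`
    (one per experiment).  Percentages are computed per cell and averaged;
    bootstrap CIs and sign-rank/sign/t tests run on the per-cell vectors.
    Cells whose direct fit did not converge or has A <= 0 are dropped
    pairwise and counted in ``n_excluded``.
    """
    cells, excluded = _usable_cells(characteristic_sets)
    if not cells:
        raise ValueError("no usable comparison cells")
    rows = []
    for types in cells:
        a_dir, a_ind = types["direct"].A, types["indirect"].A
        a_coh, a_inc = types["coherent"].A, types["incoherent"].A
        row = {
            "total_fac_pct": percent_change(a_dir, a_coh),
            "superadd_pct": 100.0 * (a_coh - (a_dir + a_ind)) / a_dir,
            "linear_pct": 100.0 * a_ind / a_dir,
            "incoh_vs_direct_pct": percent_change(a_dir, a_inc),
        }
        row["specificity_pct"] = percent_change(a_inc, a_coh) if a_inc > 0 else np.nan
        rows.append(row)
    per_cell = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    estimates = {
        name: estimate(per_cell[name].dropna().to_numpy(), stat="mean",
                       n_boot=n_boot, alpha=alpha, seed=rng)
        for name in per_cell.columns
    }
    return ContextMetrics(
        estimates=estimates, per_cell=per_cell, n_excluded=excluded,
        provenance={"n_boot": n_boot, "alpha": alpha, "seed": seed,
                    "n_cells": len(cells), "n_excluded": excluded},
    )


def spread_metrics(
    characteristic_sets,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
) -> ContextMetrics:
    """Spread-change metrics (joint, sigma_x, sigma_y) for both contrasts.

    Percent changes of the coherent fit's spreads relative to the direct fit
    (``coh_vs_dir``) and to the incoherent fit (``coh_vs_incoh``), per cell,
    aggregated like the amplitude metrics.
    """
    cells, excluded = _usable_cells(characteristic_sets)
    if not cells:
        raise ValueError("no usable comparison cells")
    rows = []
    for types in cells:
        coh, dirg, inc = types["coherent"], types["direct"], types["incoherent"]
        rows.append({
            "spread_joint_pct_coh_vs_dir": percent_change(dirg.joint_spread, coh.joint_spread),
            "spread_x_pct_coh_vs_dir": percent_change(dirg.sigma_x, coh.sigma_x),
            "spread_y_pct_coh_vs_dir": percent_change(dirg.sigma_y, coh.sigma_y),
            "spread_joint_pct_coh_vs_incoh": percent_change(inc.joint_spread, coh.joint_spread),
            "spread_x_pct_coh_vs_incoh": percent_change(inc.sigma_x, coh.sigma_x),
            "spread_y_pct_coh_vs_incoh": percent_change(inc.sigma_y, coh.sigma_y),
        })
    per_cell = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    estimates = {
        name: estimate(per_cell[name].to_numpy(), stat="mean",
                       n_boot=n_boot, alpha=alpha, seed=rng)
        for name in per_cell.columns
    }
    return ContextMetrics(
        estimates=estimates, per_cell=per_cell, n_excluded=excluded,
        provenance={"n_boot": n_boot, "alpha": alpha, "seed": seed,
                    "n_cells": len(cells), "n_excluded": excluded},
    )
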