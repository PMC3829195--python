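"""Percentile-ROI extraction and time-resolved analysis of evoked activity.

Two non-overlapping regions of interest are defined per movie from the
single-condition (no-context) activity profiles: the pixels within the
highest 5th percentile of each profile.  ROI-mean time courses are extracted
per activation type, resampled to the 200 Hz analysis resolution, aggregated
across (location, movie) cells by the per-bin median with a sign-rank test
per bin, and the cross-location Pearson correlations r_single, r_coherent
and r_incoherent are computed over the stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_evo import EvokedDataset
from .preprocess import ActivityProfile
from .stats import signrank_p

ANALYSIS_RATE_HZ = 200.0
ROI_PERCENTILE = 95.0


class DegenerateRoiError(ValueError):
    """ROI selection produced an empty or undefined mask."""


@dataclass
class RoiPair:
    """Non-overlapping percentile ROI masks for locations A and B."""

    mask_A: np.ndarray
    mask_B: np.ndarray
    source_conditions: tuple[str, str]
    percentile: float = ROI_PERCENTILE

    def mask(self, location: str) -> np.ndarray:
        if location == "A":
            return self.mask_A
        if location == "B":
            return self.mask_B
        raise KeyError(f"location must be 'A' or 'B', got {location!r}")


@dataclass
class TypeTraces:
    """Per-type aggregated ROI time courses at analysis resolution.

    ``median[type]`` is the across-cell median trace; ``significant[type]``
    flags bins whose per-cell values differ from zero (sign-rank, the given
    alpha).  ``diff_median``/``diff_significant`` hold the pairwise
    coherent-direct and coherent-incoherent difference traces.
    """

    times_ms: np.ndarray
    median: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]
    per_cell: dict[str, np.ndarray]  # [n_cells, n_bins]
    diff_median: dict[str, np.ndarray] = field(default_factory=dict)
    diff_significant: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: float = 0.05


def percentile_threshold(values: np.ndarray, pct: float) -> float:
    """Boundary-inclusive percentile threshold (lower interpolation).

    The threshold is the element at sorted position floor((n-1) * pct/100),
    so pixels *at* the boundary value are inside the ROI.
    """
    return float(np.percentile(np.asarray(values).ravel(), pct, method="lower"))


def define_roi(
    profile_A: ActivityProfile,
    profile_B: ActivityProfile,
    pct: float = ROI_PERCENTILE,
) -> RoiPair:
    """Top-percentile ROIs from the two single-condition profiles.

    Each mask keeps pixels with value >= the pct-th percentile of its own
    profile (boundary inclusive); pixels claimed by both masks go to the
    location with the larger profile value there.
    """
    vA, vB = profile_A.values, profile_B.values
    if vA.shape != vB.shape:
        raise ValueError("profiles must share a grid")
    if np.ptp(vA) == 0 or np.ptp(vB) == 0:
        raise DegenerateRoiError("constant profile: percentile ROI undefined")
    mA = vA >= percentile_threshold(vA, pct)
    mB = vB >= percentile_threshold(vB, pct)
    overlap = mA & mB
    if overlap.any():
        a_wins = vA >= vB
        mA = mA & (~overlap | a_wins)
        mB = mB & (~overlap | ~a_wins)
    if not mA.any() or not mB.any():
        raise DegenerateRoiError("empty ROI after overlap resolution")
    return RoiPair(mask_A=mA, mask_B=mB,
                   source_conditions=(profile_A.condition, profile_B.condition),
                   percentile=pct)


def resample_trace(trace: np.ndarray, rate_in: float, rate_out: float = ANALYSIS_RATE_HZ,
                   t0_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation resampling of a trace onto a new time base.

    Returns ``(times_ms, resampled)`` with times relative to the sample at
    ``t0_index`` (stimulus onset).  Linear interpolation preserves the
    amplitude of band-limited content well below the Nyquist rate (under 1%
    loss at 5 Hz for a 220 -> 200 Hz conversion) without edge transients.
    """
    n = trace.shape[-1]
    t_in = (np.arange(n) - t0_index) / rate_in
    eps = 1e-9  # guard against fencepost loss at exact rate ratios
    t_out = np.arange(np.ceil(t_in[0] * rate_out - eps),
                      np.floor(t_in[-1] * rate_out + eps) + 1) / rate_out
    out = np.interp(t_out, t_in, trace)
    return t_out * 1000.0, out


def roi_trace(ds: EvokedDataset, cond: str, mask: np.ndarray,
              rate_out: float = ANALYSIS_RATE_HZ) -> tuple[np.ndarray, np.ndarray]:
    """ROI-mean evoked time course, resampled to the analysis rate.

    ``mask`` is a ``ys x xs`` boolean image; the spatial mean over its pixels
    is taken per sample (masks use the dataset's column-major flattening),
    then the trial-averaged trace is resampled.  Returns ``(times_ms, trace)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateRoiError("empty ROI mask")
    if mask.shape != (ds.ys, ds.xs):
        raise ValueError(f"mask shape {mask.shape} does not match grid ({ds.ys}, {ds.xs})")
    flat = mask.flatten(order="F")
    trace = ds.data[flat, :, ds.cond_index(cond)].mean(axis=0)
    return resample_trace(trace, ds.frame_rate_hz, rate_out, t0_index=ds.prestim_samples)


#: condition and ROI location per activation type for each (location, movie) cell.
_TRACE_CONDITIONS: dict[tuple[str, int], dict[str, str]] = {
    ("A", 1): {"direct": "A1", "indirect": "B1", "coherent": "A1B1", "incoherent": "A1B2"},
    ("A", 2): {"direct": "A2", "indirect": "B2", "coherent": "A2B2", "incoherent": "A2B1"},
    ("B", 1): {"direct": "B1", "indirect": "A1", "coherent": "A1B1", "incoherent": "A2B1"},
    ("B", 2): {"direct": "B2", "indirect": "A2", "coherent": "A2B2", "incoherent": "A1B2"},
}


def _bin_signrank(per_cell: np.ndarray, alpha: float) -> np.ndarray:
    """Per-bin sign-rank significance flags for a cells x bins matrix."""
    flags = np.zeros(per_cell.shape[1], dtype=bool)
    for j in range(per_cell.shape[1]):
        col = per_cell[:, j]
        if np.any(col != 0):
            flags[j] = signrank_p(col) < alpha
    return flags


def type_traces(
    datasets: EvokedDataset | list[EvokedDataset],
    rois: RoiPair | list[RoiPair],
    alpha: float = 0.05,
) -> TypeTraces:
    """Aggregated per-type time courses with per-bin sign-rank tests.

    For every (location, movie) cell of every experiment, the trace of each
    activation type is read from its matching condition through that
    location's ROI; the across-cell median is reported per bin together with
    a sign-rank test against zero.  Pairwise coherent-direct and
    coherent-incoherent differences are computed per cell before aggregation.
    """
    ds_list = datasets if isinstance(datasets, list) else [datasets]
    roi_list = rois if isinstance(rois, list) else [rois]
    if len(ds_list) != len(roi_list):
        raise ValueError("need one RoiPair per dataset")
    per_cell: dict[str, list[np.ndarray]] = {t: [] for t in ("direct", "indirect", "coherent", "incoherent")}
    times_ms = None
    for ds, roi in zip(ds_list, roi_list):
        missing = [c for m in _TRACE_CONDITIONS.values() for c in m.values() if c not in ds.cond_map]
        if missing:
            raise ValueError(f"missing conditions for time-course analysis: {sorted(set(missing))}")
        for (loc, movie), mapping in _TRACE_CONDITIONS.items():
            for typ, cond in mapping.items():
                t, tr = roi_trace(ds, cond, roi.mask(loc))
                per_cell[typ].append(tr)
                times_ms = t
    mats = {t: np.vstack(v) for t, v in per_cell.items()}
    median = {t: np.median(m, axis=0) for t, m in mats.items()}
    significant = {t: _bin_signrank(m, alpha) for t, m in mats.items()}
    diffs = {
        "coherent_minus_direct": mats["coherent"] - mats["direct"],
        "coherent_minus_incoherent": mats["coherent"] - mats["incoherent"],
    }
    return TypeTraces(
        times_ms=times_ms,
        median=median,
        significant=significant,
        per_cell=mats,
        diff_median={k: np.median(v, axis=0) for k, v in diffs.items()},
        diff_significant={k: _bin_signrank(v, alpha) for k, v in diffs.items()},
        alpha=alpha,
    )


def _stim_window(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    return (times_ms >= window_ms[0]) & (times_ms < window_ms[1])


def timecourse_correlations(
    ds: EvokedDataset,
    roi: RoiPair,
    window_ms: tuple[float, float] = (0.0, 750.0),
) -> pd.DataFrame:
    """Cross-location trace correlations per movie: r_single / r_coherent / r_incoherent.

    r_single correlates location A's trace under A-alone with location B's
    trace under B-alone (same movie); r_coherent correlates both locations'
    traces within the coherent pair; r_incoherent within the incoherent pair
    containing that movie at location A.  Pearson correlation over the
    stimulus window (prestim excluded, where traces are zero by
    construction).  Zero-variance traces yield NaN.
    """
    def corr(c1: str, c2: str) -> float:
        t, a = roi_trace(ds, c1, roi.mask_A)
        _, b = roi_trace(ds, c2, roi.mask_B)
        sel = _stim_window(t, window_ms)
        a, b = a[sel], b[sel]
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    rows = []
    for movie, (single_A, single_B, coherent, incoherent) in {
        1: ("A1", "B1", "A1B1", "A1B2"),
        2: ("A2", "B2", "A2B2", "A2B1"),
    }.items():
        rows.append({
            "movie": movie,
            "r_single": corr(single_A, single_B),
            "r_coherent": corr(coherent, coherent),
            "r_incoherent": corr(incoherent, incoherent),
        })
    return pd.DataFrame(rows)
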