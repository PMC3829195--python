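"""End-to-end convenience orchestration: generate -> preprocess -> fit -> metrics."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .context_metrics import CharacteristicSet, ContextMetrics, build_characteristics, facilitation_metrics, spread_metrics
from .io_evo import EvokedDataset
from .preprocess import preprocess_experiment, time_average
from .profile_fit import TwoSpotFit, fit_experiment
from .synthetic import GroundTruth, SyntheticConfig, generate_experiment
from .timecourse import RoiPair, define_roi, timecourse_correlations


@dataclass
class ExperimentResult:
    """Everything the pipeline derives from one experiment."""

    dataset: EvokedDataset
    fits: dict[str, TwoSpotFit]
    characteristics: CharacteristicSet
    roi: dict[int, RoiPair]          # per movie
    correlations: pd.DataFrame
    ground_truth: GroundTruth | None = None


def analyze_dataset(
    ds: EvokedDataset,
    approx_centers: tuple[tuple[float, float], tuple[float, float]],
    window_ms: tuple[float, float] = (0.0, 750.0),
    **fit_kwargs,
) -> ExperimentResult:
    """Fit profiles, build characteristics, ROIs and correlations for one dataset."""
    fits = fit_experiment(ds, approx_centers, window_ms=window_ms, **fit_kwargs)
    cs = build_characteristics(fits)
    rois: dict[int, RoiPair] = {}
    corr_frames = []
    for movie, (cond_a, cond_b) in {1: ("A1", "B1"), 2: ("A2", "B2")}.items():
        roi = define_roi(time_average(ds, cond_a, window_ms), time_average(ds, cond_b, window_ms))
        rois[movie] = roi
        frame = timecourse_correlations(ds, roi, window_ms=window_ms)
        corr_frames.append(frame[frame["movie"] == movie])
    return ExperimentResult(
        dataset=ds, fits=fits, characteristics=cs, roi=rois,
        correlations=pd.concat(corr_frames, ignore_index=True),
    )


def run_synthetic_experiment(cfg: SyntheticConfig, **fit_kwargs) -> ExperimentResult:
    """Generate one synthetic experiment and run the full analysis on it."""
    stacks, truth = generate_experiment(cfg)
    ds = preprocess_experiment(stacks, ys=cfg.ys, xs=cfg.xs)
    centers = (tuple(cfg.centerA), tuple(cfg.centerB))
    window = (0.0, cfg.analysis_ms)
    result = analyze_dataset(ds, centers, window_ms=window, **fit_kwargs)
    result.ground_truth = truth
    return result


def metrics_across_experiments(
    results: list[ExperimentResult],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[ContextMetrics, ContextMetrics]:
    """Facilitation and spread metrics pooled over several experiments."""
    sets = [r.characteristics for r in results]
    return (
        facilitation_metrics(sets, n_boot=n_boot, alpha=alpha, seed=seed),
        spread_metrics(sets, n_boot=n_boot, alpha=alpha, seed=seed),
    )
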