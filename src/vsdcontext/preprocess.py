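"""Raw trial stacks -> trial-averaged evoked dF/F -> time-averaged spatial profiles.

The two-step correction:

1. divisive prestimulus normalization — every pixel's time series is divided,
   per trial, by that pixel's mean during the prestimulus interval (removes
   static illumination differences);
2. blank correction — the trial-averaged blank signal is subtracted and the
   difference divided by it, ``evoked = (stim - blank) / blank`` per pixel and
   sample (removes heartbeat/respiration artifacts shared with blanks).

Both steps run per trial; the outcome is then averaged across trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io_evo import EVO_CONDITION_ORDER, EvokedDataset
from .synthetic import TrialStack


class DegeneratePixelError(ValueError):
    """Nonpositive prestimulus or blank mean at some pixels."""

    def __init__(self, message: str, pixels: np.ndarray):
        super().__init__(f"{message}: pixel indices {pixels[:20].tolist()}"
                         + ("..." if pixels.size > 20 else ""))
        self.pixels = pixels


@dataclass
class ActivityProfile:
    """Time-averaged spatial map of evoked dF/F for one condition."""

    values: np.ndarray  # [ys, xs]
    condition: str
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity profile contains non-finite values")


def prestim_normalize(stack: TrialStack) -> TrialStack:
    """Divide each pixel's series by its own prestimulus mean, per trial."""
    n_pre = stack.prestim_samples
    if n_pre < 2:
        raise ValueError(f"need >= 2 prestimulus samples, got {n_pre}")
    pre_mean = stack.frames[:, :n_pre, :].mean(axis=1)  # [n_px, n_trials]
    bad = np.unique(np.nonzero(pre_mean <= 0)[0])
    if bad.size:
        raise DegeneratePixelError("nonpositive prestimulus mean", bad)
    return dataclasses.replace(stack, frames=stack.frames / pre_mean[:, None, :])


def mean_blank(*blanks: TrialStack) -> np.ndarray:
    """Average blank signal ``[n_px, n_time]`` over trials and blank conditions."""
    if not blanks:
        raise ValueError("at least one blank stack is required")
    return np.concatenate([b.frames for b in blanks], axis=2).mean(axis=2)


def blank_correct(stim: TrialStack, blank: TrialStack | np.ndarray, mode: str = "per_sample") -> TrialStack:
    """Evoked dF/F: subtract the average blank and normalize by it, per trial.

    ``mode='per_sample'`` (default) divides by the blank at the same pixel and
    sample, which cancels time-varying artifacts shared with blanks;
    ``mode='temporal_mean'`` divides by the blank's temporal mean per pixel.
    """
    blank_avg = blank if isinstance(blank, np.ndarray) else blank.frames.mean(axis=2)
    if blank_avg.shape != stim.frames.shape[:2]:
        raise ValueError(
            f"blank shape {blank_avg.shape} does not match stimulus {stim.frames.shape[:2]}"
        )
    bad = np.unique(np.nonzero(~(blank_avg > 0))[0])
    if bad.size:
        raise DegeneratePixelError("nonpositive mean blank", bad)
    if mode == "per_sample":
        # (stim - b) / b computed as stim / b - 1 (one full-size pass)
        evoked = stim.frames / blank_avg[:, :, None]
        evoked -= 1.0
    elif mode == "temporal_mean":
        denom = blank_avg.mean(axis=1)[:, None, None]
        evoked = (stim.frames - blank_avg[:, :, None]) / denom
    else:
        raise ValueError(f"unknown blank mode {mode!r}")
    return dataclasses.replace(stim, frames=evoked)


def average_trials(stack: TrialStack) -> np.ndarray:
    """Arithmetic mean over trials: ``[n_px, n_time]``."""
    if stack.n_trials < 1:
        raise ValueError("need at least one trial")
    return stack.frames.mean(axis=2)


def preprocess_experiment(
    stacks: dict[str, TrialStack],
    ys: int | None = None,
    xs: int | None = None,
    blank_mode: str = "per_sample",
) -> EvokedDataset:
    """Full preprocessing of one experiment's trial stacks.

    Normalizes every stack by its prestimulus means, builds the average blank
    from both blank conditions, blank-corrects each condition per trial and
    averages across trials.  Blank conditions themselves are corrected against
    the joint average blank (their evoked values fluctuate around zero).
    """
    blanks = [c for c in stacks if c.startswith("blank")]
    if not blanks:
        raise ValueError("experiment has no blank condition")

    def normalized_trial_mean(st: TrialStack) -> np.ndarray:
        # mean over trials of the per-trial prestim-normalized frames,
        # computed in one pass without a full-size intermediate
        n_pre = st.prestim_samples
        if n_pre < 2:
            raise ValueError(f"need >= 2 prestimulus samples, got {n_pre}")
        pre = st.frames[:, :n_pre, :].mean(axis=1)
        bad = np.unique(np.nonzero(pre <= 0)[0])
        if bad.size:
            raise DegeneratePixelError("nonpositive prestimulus mean", bad)
        return np.einsum("ptr,pr->pt", st.frames, 1.0 / pre) / st.n_trials

    norm = {cond: normalized_trial_mean(st) for cond, st in stacks.items()}
    n_blank_trials = sum(stacks[c].n_trials for c in blanks)
    blank_avg = sum(norm[c] * stacks[c].n_trials for c in blanks) / n_blank_trials
    bad = np.unique(np.nonzero(~(blank_avg > 0))[0])
    if bad.size:
        raise DegeneratePixelError("nonpositive mean blank", bad)

    conds = [c for c in EVO_CONDITION_ORDER if c in stacks]
    conds += [c for c in stacks if c not in conds]
    first = next(iter(stacks.values()))
    if ys is None or xs is None:
        if first.config is None:
            raise ValueError("grid dimensions required when stacks carry no config")
        ys, xs = first.config.ys, first.config.xs
    data = np.empty((first.n_px, first.n_time, len(conds)))
    for i, cond in enumerate(conds):
        # blank correction is affine per trial (fixed subtrahend/denominator),
        # so it commutes exactly with trial averaging; averaging first avoids
        # a full-size intermediate per condition
        if blank_mode == "per_sample":
            data[:, :, i] = norm[cond] / blank_avg - 1.0
        elif blank_mode == "temporal_mean":
            data[:, :, i] = (norm[cond] - blank_avg) / blank_avg.mean(axis=1)[:, None]
        else:
            raise ValueError(f"unknown blank mode {blank_mode!r}")
    return EvokedDataset(
        data=data,
        ys=ys,
        xs=xs,
        frame_rate_hz=first.frame_rate_hz,
        prestim_samples=first.prestim_samples,
        cond_map={c: i for i, c in enumerate(conds)},
    )


def time_average(
    ds: EvokedDataset,
    cond: str,
    window_ms: tuple[float, float] = (0.0, 750.0),
    window_includes_prestim: bool = False,
) -> ActivityProfile:
    """Mean evoked map over a temporal window, as a ``ys x xs`` image.

    The window is given in ms relative to stimulus onset (sample index
    ``prestim_samples`` is t = 0).  With ``window_includes_prestim`` the
    window is taken relative to trial onset instead, so ``(0, 750)`` then
    covers the prestimulus interval plus the first 550 ms of stimulation.
    """
    lo_ms, hi_ms = window_ms
    if hi_ms <= lo_ms:
        raise ValueError(f"empty averaging window {window_ms}")
    offset = 0 if window_includes_prestim else ds.prestim_samples
    lo = offset + int(round(lo_ms / 1000.0 * ds.frame_rate_hz))
    hi = offset + int(round(hi_ms / 1000.0 * ds.frame_rate_hz))
    lo, hi = max(lo, 0), min(hi, ds.n_time)
    if hi <= lo:
        raise ValueError(f"window {window_ms} ms selects no samples")
    c = ds.cond_index(cond)
    mean_map = ds.data[:, lo:hi, c].mean(axis=1).reshape(ds.ys, ds.xs, order="F")
    return ActivityProfile(values=mean_map, condition=cond, window_ms=(float(lo_ms), float(hi_ms)))
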