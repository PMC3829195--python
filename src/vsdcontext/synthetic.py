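"""Synthetic raw-trial generator with the statistical structure the analysis assumes.

The generator emulates a mesoscopic voltage-sensitive-dye experiment in which
natural-movie patches drive two well-separated Gaussian activity spots on the
cortical surface:

* a static multiplicative illumination gain field per pixel;
* a prestimulus baseline interval with no evoked activity;
* evoked activity as two spatially Gaussian spots, each modulated in time by a
  low-pass-filtered "movie drive" signal; drives for the same movie at the two
  locations share a common component with weight sqrt(c) so their expected
  correlation equals ``drive_coh``;
* a multiplicative facilitation gain applied to both spots in paired-patch
  conditions (separately for coherent and incoherent pairs), plus a convex
  lateral-coupling term mixing a fraction of the distant patch's drive into
  each site's effective drive;
* a small "indirect" copy of the stimulated patch's drive at the distant,
  non-stimulated spot in single conditions;
* a heartbeat-like sinusoidal artifact phase-locked identically across all
  trials and conditions (including blanks), which is what makes blank
  subtraction exact;
* i.i.d. Gaussian sensor noise per pixel/sample/trial; and
* blank (no-stimulus) trials.

Every draw is derived from ``SyntheticConfig.seed`` through keyed
``numpy.random.SeedSequence`` streams, so the same (movie, location) drive is
bit-identical across conditions and a whole experiment is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage
import scipy.signal

from .io_evo import EVO_CONDITION_ORDER, STIMULUS_CONDITIONS

#: FWHM of a Gaussian in units of its standard deviation.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: (location, movie) patches stimulated in each condition.
CONDITION_PATCHES: dict[str, tuple[tuple[str, int], ...]] = {
    "blank1": (),
    "blank2": (),
    "A1": (("A", 1),),
    "B1": (("B", 1),),
    "A2": (("A", 2),),
    "B2": (("B", 2),),
    "A1B1": (("A", 1), ("B", 1)),
    "A2B2": (("A", 2), ("B", 2)),
    "A1B2": (("A", 1), ("B", 2)),
    "A2B1": (("A", 2), ("B", 1)),
}

COHERENT_CONDITIONS = ("A1B1", "A2B2")
INCOHERENT_CONDITIONS = ("A1B2", "A2B1")


class ConditionError(ValueError):
    """Unknown stimulation condition label."""


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic experiment.

    Geometry defaults echo a ~10 x 5 mm imaged field at ~0.05 mm/px; the two
    spot centers are separated along the antero-posterior (row) axis by
    ``sep_fwhm`` FWHMs of the mean spot sigma, mirroring the 2.5-FWHM
    aperture separation of the stimulus design.  Amplitudes are in dF/F-like
    fractional units.
    """

    ys: int = 90
    xs: int = 190
    mm_per_px: float = 0.05
    frame_rate_hz: float = 220.0
    prestim_ms: float = 200.0
    stim_ms: float = 2000.0
    analysis_ms: float = 750.0
    centerA: tuple[float, float] | None = None  # (row, col)
    centerB: tuple[float, float] | None = None
    spot_sigma_px: tuple[float, float] = (6.0, 6.0)  # (sigma_x, sigma_y)
    spot_rho: float = 0.0
    sep_fwhm: float = 2.5
    amp_direct: float = 2.3e-4
    amp_indirect_frac: float = 0.03
    facilitation_gain_coh: float = 1.45
    facilitation_gain_incoh: float = 1.2
    pair_coupling_frac: float = 0.15
    spread_gain_coh: tuple[float, float] = (1.0, 1.18)   # (x, y) sigma scaling, coherent pairs
    spread_gain_incoh: tuple[float, float] = (1.0, 1.085)
    drive_coh: float = 0.6
    drive_cutoff_hz: float = 25.0
    drive_offset: float = 1.5
    heartbeat_hz: float = 2.5
    heartbeat_amp: float = 0.01
    gain_field_amp: float = 0.2
    noise_sd: float = 6.5e-4
    n_trials: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.drive_coh <= 1.0):
            raise ValueError("drive_coh must lie in [0, 1]")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        for name in ("amp_direct", "heartbeat_amp", "gain_field_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.centerA is None or self.centerB is None:
            sep_px = self.sep_fwhm * self.fwhm_px
            r0 = (self.ys - 1) / 2.0
            c0 = (self.xs - 1) / 2.0
            self.centerA = (r0 - sep_px / 2.0, c0)
            self.centerB = (r0 + sep_px / 2.0, c0)
        dist = float(np.hypot(self.centerA[0] - self.centerB[0], self.centerA[1] - self.centerB[1]))
        if abs(dist - self.sep_fwhm * self.fwhm_px) > 1.0:
            raise ValueError(
                f"center separation {dist:.2f} px disagrees with sep_fwhm={self.sep_fwhm} "
                f"(expected {self.sep_fwhm * self.fwhm_px:.2f} px, tolerance 1 px)"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def fwhm_px(self) -> float:
        return FWHM_PER_SIGMA * float(np.mean(self.spot_sigma_px))

    @property
    def prestim_samples(self) -> int:
        return int(round(self.prestim_ms / 1000.0 * self.frame_rate_hz))

    @property
    def n_time(self) -> int:
        return int(round((self.prestim_ms + self.stim_ms) / 1000.0 * self.frame_rate_hz))

    @property
    def analysis_samples(self) -> int:
        return int(round(self.analysis_ms / 1000.0 * self.frame_rate_hz))

    @property
    def n_px(self) -> int:
        return self.ys * self.xs

    def separation_fwhm(self) -> float:
        """Measured center separation in FWHM units (should equal sep_fwhm)."""
        dist = np.hypot(self.centerA[0] - self.centerB[0], self.centerA[1] - self.centerB[1])
        return float(dist / self.fwhm_px)

    @classmethod
    def small(cls, **overrides) -> "SyntheticConfig":
        """Scaled-down grid (32 x 64, 800 ms stimulus) for fast runs."""
        params = dict(
            ys=32, xs=64, spot_sigma_px=(2.5, 2.5), stim_ms=800.0, mm_per_px=0.15,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class TrialStack:
    """Raw fluorescence frames for one condition: ``[n_px, n_time, n_trials]``."""

    frames: np.ndarray
    condition: str
    frame_rate_hz: float
    prestim_samples: int
    config: SyntheticConfig | None = None

    @property
    def n_px(self) -> int:
        return self.frames.shape[0]

    @property
    def n_time(self) -> int:
        return self.frames.shape[1]

    @property
    def n_trials(self) -> int:
        return self.frames.shape[2]


@dataclass
class GroundTruth:
    """True generative parameters exported alongside a synthetic experiment.

    ``spots[(condition, location)]`` holds the parameters of the expected
    time-averaged (over the analysis window) spatial Gaussian at that
    location: keys A, mu_x, mu_y, sigma_x, sigma_y, rho.  ``drives`` maps
    ``(movie, location)`` to the full-length drive series.
    """

    spots: dict[tuple[str, str], dict[str, float]]
    drives: dict[tuple[int, str], np.ndarray]
    drive_corr: float
    facilitation_gain_coh: float
    facilitation_gain_incoh: float
    amp_indirect_frac: float
    config: SyntheticConfig = None

    def expected_facilitation_pct(self) -> float:
        """Facilitation implied by the coherent gain alone, in percent."""
        return 100.0 * (self.facilitation_gain_coh - 1.0)


# ---------------------------------------------------------------------------
# Keyed RNG streams
# ---------------------------------------------------------------------------

_KEYS = {"gain_field": 1, "heartbeat": 2, "drive_shared": 3, "drive_indep": 4, "noise": 5}
_LOC_IDX = {"A": 0, "B": 1}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def gaussian_spot(
    ys: int, xs: int, center: tuple[float, float],
    sigma: tuple[float, float], rho: float = 0.0, amplitude: float = 1.0,
) -> np.ndarray:
    """Unit-or-scaled rotated Gaussian image; ``center`` is (row, col).

    x is the column (medio-lateral) coordinate and y the row
    (antero-posterior) coordinate, matching the fitted parameterisation.
    """
    rows = np.arange(ys)[:, None]
    cols = np.arange(xs)[None, :]
    dy = rows - center[0]
    dx = cols - center[1]
    sx, sy = sigma
    expo = dx ** 2 / (2.0 * sx ** 2) + dy ** 2 / (2.0 * sy ** 2) + rho * dx * dy
    return amplitude * np.exp(-expo)


def make_gain_field(cfg: SyntheticConfig) -> np.ndarray:
    """Static illumination gain: 1 + smooth zero-mean field, strictly positive."""
    rng = _rng(cfg.seed, _KEYS["gain_field"])
    raw = rng.standard_normal((cfg.ys, cfg.xs))
    smooth = scipy.ndimage.gaussian_filter(raw, sigma=max(cfg.ys, cfg.xs) / 8.0, mode="reflect")
    if np.ptp(smooth) > 0:
        smooth = smooth / np.max(np.abs(smooth))
    amp = min(cfg.gain_field_amp, 0.5)  # keep gain bounded away from zero
    return 1.0 + amp * smooth


def make_heartbeat(cfg: SyntheticConfig) -> np.ndarray:
    """Heartbeat-like artifact series, phase-locked across trials/conditions."""
    rng = _rng(cfg.seed, _KEYS["heartbeat"])
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(cfg.n_time) / cfg.frame_rate_hz
    return cfg.heartbeat_amp * np.sin(2.0 * np.pi * cfg.heartbeat_hz * t + phase)


def _lowpass_noise(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = cfg.frame_rate_hz / 2.0
    if cfg.drive_cutoff_hz >= nyq:
        out = white
    else:
        b, a = scipy.signal.butter(4, cfg.drive_cutoff_hz / nyq)
        out = scipy.signal.filtfilt(b, a, white)
    out = out - out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def make_drive(cfg: SyntheticConfig, movie_id: int, location: str) -> np.ndarray:
    """Temporal drive for one movie patch at one cortical location.

    Low-pass-filtered Gaussian noise, zero during the prestimulus interval,
    offset by ``drive_offset`` during the stimulus so evoked activity is net
    positive.  Same-movie drives at locations A and B mix a shared component
    with weight sqrt(c), c = ``drive_coh``, so their expected Pearson
    correlation over the stimulus window equals c; different movies are
    independent.  Deterministic given ``cfg.seed``.
    """
    if location not in _LOC_IDX:
        raise ValueError(f"location must be 'A' or 'B', got {location!r}")
    n_stim = cfg.n_time - cfg.prestim_samples
    shared = _lowpass_noise(n_stim, cfg, _rng(cfg.seed, _KEYS["drive_shared"], movie_id))
    indep = _lowpass_noise(
        n_stim, cfg, _rng(cfg.seed, _KEYS["drive_indep"], movie_id, _LOC_IDX[location])
    )
    c = cfg.drive_coh
    raw = np.sqrt(c) * shared + np.sqrt(1.0 - c) * indep
    raw = raw - raw.mean()
    sd = raw.std()
    if sd > 0:
        raw = raw / sd
    drive = np.zeros(cfg.n_time)
    drive[cfg.prestim_samples:] = cfg.drive_offset + raw
    return drive


def _effective_drives(cfg: SyntheticConfig, condition: str) -> dict[str, tuple[float, np.ndarray, tuple[float, float]]]:
    """Per stimulated/leaked location: (amplitude, drive series, sigma).

    Returns ``{location: (peak_amp, drive, (sigma_x, sigma_y))}`` for the
    noiseless evoked term of ``condition``.
    """
    patches = CONDITION_PATCHES.get(condition)
    if patches is None:
        raise ConditionError(f"unknown condition {condition!r}; known: {sorted(CONDITION_PATCHES)}")
    out: dict[str, tuple[float, np.ndarray, tuple[float, float]]] = {}
    base_sigma = tuple(cfg.spot_sigma_px)
    if len(patches) == 1:
        (loc, movie), = patches
        other = "B" if loc == "A" else "A"
        d = make_drive(cfg, movie, loc)
        out[loc] = (cfg.amp_direct, d, base_sigma)
        if cfg.amp_indirect_frac != 0.0:
            out[other] = (cfg.amp_indirect_frac * cfg.amp_direct, d, base_sigma)
    elif len(patches) == 2:
        if condition in COHERENT_CONDITIONS:
            gain, sgx, sgy = cfg.facilitation_gain_coh, *cfg.spread_gain_coh
        else:
            gain, sgx, sgy = cfg.facilitation_gain_incoh, *cfg.spread_gain_incoh
        sigma = (base_sigma[0] * sgx, base_sigma[1] * sgy)
        k = cfg.pair_coupling_frac
        drives = {loc: make_drive(cfg, movie, loc) for loc, movie in patches}
        locs = [loc for loc, _ in patches]
        for loc in locs:
            other = locs[1] if loc == locs[0] else locs[0]
            eff = (1.0 - k) * drives[loc] + k * drives[other]
            out[loc] = (gain * cfg.amp_direct, eff, sigma)
    return out


def render_condition(cfg: SyntheticConfig, condition: str, rng: np.random.Generator | None = None) -> TrialStack:
    """Render raw trial frames for one condition.

    ``frames = gain_field * (1 + evoked + heartbeat + noise)`` with the
    evoked term zero during prestim and for blanks.  ``rng`` supplies the
    sensor noise; when omitted a stream keyed on (seed, condition index) is
    used so standalone renders match :func:`generate_experiment`.
    """
    if condition not in CONDITION_PATCHES:
        raise ConditionError(f"unknown condition {condition!r}; known: {sorted(CONDITION_PATCHES)}")
    if rng is None:
        rng = _rng(cfg.seed, _KEYS["noise"], EVO_CONDITION_ORDER.index(condition))
    gain = make_gain_field(cfg).flatten(order="F")  # column-major space axis
    hb = make_heartbeat(cfg)

    evoked = np.zeros((cfg.n_px, cfg.n_time))
    centers = {"A": cfg.centerA, "B": cfg.centerB}
    for loc, (amp, drive, sigma) in _effective_drives(cfg, condition).items():
        spot = gaussian_spot(cfg.ys, cfg.xs, centers[loc], sigma, cfg.spot_rho).flatten(order="F")
        evoked += amp * spot[:, None] * drive[None, :]

    modulation = 1.0 + evoked + hb[None, :]
    frames = np.empty((cfg.n_px, cfg.n_time, cfg.n_trials))
    for trial in range(cfg.n_trials):
        eps = rng.standard_normal((cfg.n_px, cfg.n_time)) * cfg.noise_sd if cfg.noise_sd > 0 else 0.0
        frames[:, :, trial] = gain[:, None] * (modulation + eps)
    return TrialStack(
        frames=frames,
        condition=condition,
        frame_rate_hz=cfg.frame_rate_hz,
        prestim_samples=cfg.prestim_samples,
        config=cfg,
    )


def _window_mean(cfg: SyntheticConfig, series: np.ndarray) -> float:
    """Mean of a drive series over the analysis window after stimulus onset."""
    lo = cfg.prestim_samples
    hi = lo + cfg.analysis_samples
    return float(series[lo:hi].mean())


def ground_truth(cfg: SyntheticConfig) -> GroundTruth:
    """Expected time-averaged spot parameters and drive series for ``cfg``."""
    spots: dict[tuple[str, str], dict[str, float]] = {}
    centers = {"A": cfg.centerA, "B": cfg.centerB}
    for cond in EVO_CONDITION_ORDER:
        for loc, (amp, drive, sigma) in _effective_drives(cfg, cond).items():
            spots[(cond, loc)] = {
                "A": amp * _window_mean(cfg, drive),
                "mu_x": centers[loc][1],
                "mu_y": centers[loc][0],
                "sigma_x": sigma[0],
                "sigma_y": sigma[1],
                "rho": cfg.spot_rho,
            }
    drives = {
        (movie, loc): make_drive(cfg, movie, loc)
        for movie in (1, 2) for loc in ("A", "B")
    }
    return GroundTruth(
        spots=spots,
        drives=drives,
        drive_corr=cfg.drive_coh,
        facilitation_gain_coh=cfg.facilitation_gain_coh,
        facilitation_gain_incoh=cfg.facilitation_gain_incoh,
        amp_indirect_frac=cfg.amp_indirect_frac,
        config=cfg,
    )


def generate_experiment(cfg: SyntheticConfig) -> tuple[dict[str, TrialStack], GroundTruth]:
    """Render all 10 conditions (8 stimulus + 2 blanks) plus ground truth.

    Each condition draws its sensor noise from a child stream keyed on the
    condition index, so the whole experiment is reproducible from
    ``cfg.seed`` and conditions are statistically independent.
    """
    stacks = {cond: render_condition(cfg, cond) for cond in EVO_CONDITION_ORDER}
    return stacks, ground_truth(cfg)


# ---------------------------------------------------------------------------
# On-disk round trip (NPZ + JSON sidecar)
# ---------------------------------------------------------------------------

def save_experiment(stacks: dict[str, TrialStack], truth: GroundTruth, out_dir: str | Path) -> None:
    """Write trial stacks to ``stacks.npz`` and ground truth to ``ground_truth.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {cond: st.frames for cond, st in stacks.items()}
    first = next(iter(stacks.values()))
    arrays["_frame_rate_hz"] = np.array(first.frame_rate_hz)
    arrays["_prestim_samples"] = np.array(first.prestim_samples)
    np.savez(out / "stacks.npz", **arrays)
    gt = {
        "drive_corr": truth.drive_corr,
        "facilitation_gain_coh": truth.facilitation_gain_coh,
        "facilitation_gain_incoh": truth.facilitation_gain_incoh,
        "amp_indirect_frac": truth.amp_indirect_frac,
        "spots": {f"{cond}/{loc}": params for (cond, loc), params in truth.spots.items()},
        "config": dataclasses.asdict(truth.config) if truth.config else None,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2, sort_keys=True))


def load_experiment(in_dir: str | Path) -> dict[str, TrialStack]:
    """Read trial stacks written by :func:`save_experiment`."""
    data = np.load(Path(in_dir) / "stacks.npz")
    rate = float(data["_frame_rate_hz"])
    prestim = int(data["_prestim_samples"])
    return {
        cond: TrialStack(frames=data[cond], condition=cond, frame_rate_hz=rate, prestim_samples=prestim)
        for cond in data.files if not cond.startswith("_")
    }
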