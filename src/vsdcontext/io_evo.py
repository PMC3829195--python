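"""Reading and writing of EVO-format evoked datasets and pipeline outputs.

The deposited experiments ship as MAT files holding a struct ``Evo`` with
fields ``d`` (evoked dF/F, organised as ``[space, time, condition]``), ``ys``
and ``xs`` (grid dimensions).  The space axis is the column-major (Fortran)
flattening of a ``ys x xs`` image, i.e. the Matlab idiom
``reshape(d(:, n, m), ys, xs)``.  The ten conditions follow a fixed 1-based
ordering which is translated to 0-based labels at this I/O boundary only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io

#: Documented EVO condition ordering (1-based in the deposited files).
EVO_CONDITION_ORDER: tuple[str, ...] = (
    "blank1", "blank2",
    "A1B1", "A1", "B1",
    "A2B2", "A2", "B2",
    "A1B2", "A2B1",
)

#: Conditions with a visual stimulus (everything but the two blanks).
STIMULUS_CONDITIONS: tuple[str, ...] = EVO_CONDITION_ORDER[2:]

#: Default acquisition parameters; the EVO files do not store them.
DEFAULT_FRAME_RATE_HZ = 220.0
DEFAULT_PRESTIM_MS = 200.0


class EvoFormatError(ValueError):
    """Raised when an EVO container is missing a required field."""


class EvoShapeError(ValueError):
    """Raised when the space dimension is inconsistent with ys * xs."""


@dataclass
class EvokedDataset:
    """Trial-averaged evoked dF/F data in the EVO layout.

    Parameters
    ----------
    data
        Array ``[n_space, n_time, n_cond]`` of evoked dF/F values.
    ys, xs
        Image grid dimensions: ``ys`` rows (antero-posterior), ``xs``
        columns (medio-lateral); ``n_space == ys * xs``.
    frame_rate_hz
        Acquisition rate in samples per second.
    prestim_samples
        Number of samples before stimulus onset.
    cond_map
        Mapping condition label -> 0-based index along the condition axis.
    """

    data: np.ndarray
    ys: int
    xs: int
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    prestim_samples: int = int(round(DEFAULT_PRESTIM_MS / 1000.0 * DEFAULT_FRAME_RATE_HZ))
    cond_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise EvoShapeError(f"data must be [space, time, condition], got ndim={self.data.ndim}")
        if self.data.shape[0] != self.ys * self.xs:
            raise EvoShapeError(
                f"n_space={self.data.shape[0]} does not equal ys*xs={self.ys * self.xs}"
            )
        if not self.cond_map:
            self.cond_map = {lab: i for i, lab in enumerate(EVO_CONDITION_ORDER[: self.data.shape[2]])}

    @property
    def n_space(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def n_cond(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset (prestim is negative)."""
        idx = np.arange(self.n_time) - self.prestim_samples
        return idx * 1000.0 / self.frame_rate_hz

    def cond_index(self, cond: str) -> int:
        try:
            return self.cond_map[cond]
        except KeyError:
            raise KeyError(f"unknown condition {cond!r}; have {sorted(self.cond_map)}") from None


def read_evo(
    path: str | Path,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    prestim_ms: float = DEFAULT_PRESTIM_MS,
) -> EvokedDataset:
    """Load a deposited EVO MAT file into an :class:`EvokedDataset`.

    The documented 1-based condition ordering (1-2 blanks, 3 A1B1, 4 A1, 5 B1,
    6 A2B2, 7 A2, 8 B2, 9 A1B2, 10 A2B1) is translated into the 0-based
    ``cond_map``.  Frame rate and prestimulus interval are not stored in the
    files and are supplied by the caller (defaults 220 Hz, 200 ms).
    """
    mat = scipy.io.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    struct = None
    for key, val in mat.items():
        if key.startswith("__"):
            continue
        if hasattr(val, "_fieldnames"):
            struct = val
            break
    if struct is None:
        raise EvoFormatError(f"{path}: no Matlab struct found in file")
    for fld in ("d", "ys", "xs"):
        if fld not in struct._fieldnames:
            raise EvoFormatError(f"{path}: EVO struct is missing field {fld!r}")
    d = np.asarray(struct.d, dtype=float)
    ys, xs = int(struct.ys), int(struct.xs)
    if d.ndim == 2:  # single condition collapses the third axis on squeeze
        d = d[:, :, None]
    cond_map = {lab: i for i, lab in enumerate(EVO_CONDITION_ORDER[: d.shape[2]])}
    return EvokedDataset(
        data=d,
        ys=ys,
        xs=xs,
        frame_rate_hz=frame_rate_hz,
        prestim_samples=int(round(prestim_ms / 1000.0 * frame_rate_hz)),
        cond_map=cond_map,
    )


def write_evo(ds: EvokedDataset, path: str | Path) -> None:
    """Write a dataset back to an EVO-style MAT container (round-trippable)."""
    scipy.io.savemat(str(path), {"Evo": {"d": ds.data, "ys": ds.ys, "xs": ds.xs}})


def frame_image(ds: EvokedDataset, t: int, cond: str | int) -> np.ndarray:
    """Reshape one spatial frame into a ``ys x xs`` image.

    Uses the column-major convention of the deposited files
    (``i_space = row + ys * col``), matching Matlab's ``reshape``.
    """
    c = ds.cond_index(cond) if isinstance(cond, str) else int(cond)
    if not (0 <= t < ds.n_time):
        raise IndexError(f"sample index {t} out of range [0, {ds.n_time})")
    if not (0 <= c < ds.n_cond):
        raise IndexError(f"condition index {c} out of range [0, {ds.n_cond})")
    return ds.data[:, t, c].reshape(ds.ys, ds.xs, order="F")


def flatten_image(img: np.ndarray) -> np.ndarray:
    """Inverse of :func:`frame_image`: column-major flattening of an image."""
    return np.asarray(img).flatten(order="F")


# ---------------------------------------------------------------------------
# Metrics serialization (CSV table + JSON provenance sidecar)
# ---------------------------------------------------------------------------

METRICS_COLUMNS = ["metric", "estimate", "ci_lo", "ci_hi", "n", "p_signrank", "p_signtest", "p_ttest"]


def write_metrics(metrics, path: str | Path, provenance: Mapping | None = None) -> None:
    """Serialise a :class:`~vsdcontext.context_metrics.ContextMetrics` table.

    Writes a flat CSV (columns: metric, estimate, ci_lo, ci_hi, n, p-values)
    plus a ``.json`` sidecar holding configuration provenance.
    """
    path = Path(path)
    frame = metrics.to_frame() if hasattr(metrics, "to_frame") else pd.DataFrame(metrics, columns=METRICS_COLUMNS)
    missing = [c for c in METRICS_COLUMNS if c not in frame.columns]
    for c in missing:
        frame[c] = np.nan
    frame = frame[METRICS_COLUMNS]
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = dict(provenance or {})
    if hasattr(metrics, "provenance") and metrics.provenance:
        prov = {**_jsonable(metrics.provenance), **prov}
    sidecar.write_text(json.dumps(_jsonable(prov), indent=2, sort_keys=True))


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV written by :func:`write_metrics`."""
    return pd.read_csv(Path(path))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
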