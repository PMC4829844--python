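"""Growth kinetics and bead-assay post-processing.

Doubling times are estimated by ordinary least squares on
``log2(cell_index)`` vs time: under exponential growth the slope is
1/DT in doublings per hour.  Multiplex-immunoassay fluorescence
intensities are background-subtracted (medium-only control) and flagged
when they fall below an analyte-specific detection floor, mirroring how
barely-detectable analytes (FGF2, PDGF) are dismissed as uninformative.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .simulate import GrowthCurve

#: Per-analyte detection floors in fluorescence-intensity units; the
#: FGF2/PDGF values are the FI ranges below which the signal is treated
#: as background.
DEFAULT_DETECTION_FLOORS: dict[str, float] = {"FGF2": 26.0, "PDGF": 3.5}


@dataclasses.dataclass
class DoublingTimeFit:
    """Log-linear fit of a growth curve.

    ``doubling_time_hours`` is 1/slope and is ``None`` (with
    ``nonpositive_slope`` set) when the population is not growing.
    """

    doubling_time_hours: float | None
    slope: float                 # log2 units per hour
    intercept: float             # log2 cell index at t = 0
    window: tuple[float, float]  # hours
    r_squared: float
    n_points: int
    n_excluded: int              # points with cell_index <= 0
    nonpositive_slope: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def estimate_doubling_time(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    auto_window: bool = False,
    min_window_hours: float = 24.0,
) -> DoublingTimeFit:
    """Estimate the doubling time of a growth curve.

    Parameters
    ----------
    curve:
        (time, cell index) series.
    window:
        (start, end) hours, inclusive; defaults to the full record.
    auto_window:
        If True, pick the contiguous span of at least
        ``min_window_hours`` with the best log-linear fit (maximal R²)
        instead of using the full record — a simple exponential-phase
        detector.
    """
    t = curve.times
    y = curve.cell_index
    usable = y > 0
    n_excluded = int((~usable).sum())
    if window is None and auto_window:
        window = _best_window(t[usable], np.log2(y[usable]), min_window_hours)
    if window is not None:
        lo, hi = window
        sel = usable & (t >= lo) & (t <= hi)
    else:
        sel = usable
    if sel.sum() < 3:
        raise DataError("fewer than 3 usable points in the fit window")
    tt, yy = t[sel], np.log2(y[sel])
    res = stats.linregress(tt, yy)
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
    slope = float(res.slope)
    fit_window = (float(tt[0]), float(tt[-1]))
    if slope <= 0:
        return DoublingTimeFit(None, slope, float(res.intercept), fit_window,
                               r2, int(sel.sum()), n_excluded, nonpositive_slope=True)
    return DoublingTimeFit(1.0 / slope, slope, float(res.intercept), fit_window,
                           r2, int(sel.sum()), n_excluded)


def _best_window(t: np.ndarray, y: np.ndarray, min_hours: float) -> tuple[float, float]:
    """Contiguous (start, end) span >= min_hours maximizing the fit R².

    Exhaustive scan over all index pairs using cumulative sums, O(n²).
    """
    n = len(t)
    if n < 3:
        raise DataError("not enough points for window search")
    best = (-np.inf, (float(t[0]), float(t[-1])))
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    for i in range(n - 2):
        j = np.arange(i + 2, n)  # window [i, j] inclusive
        ok = t[j] - t[i] >= min_hours
        j = j[ok]
        if len(j) == 0:
            continue
        m = (j - i + 1).astype(float)
        st = ct[j + 1] - ct[i]
        sy = cy[j + 1] - cy[i]
        stt = ctt[j + 1] - ctt[i]
        syy = cyy[j + 1] - cyy[i]
        sty = cty[j + 1] - cty[i]
        vt = stt - st * st / m
        vy = syy - sy * sy / m
        cov = sty - st * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where((vt > 0) & (vy > 0), cov**2 / (vt * vy), 0.0)
        k = int(np.argmax(r2))
        if r2[k] > best[0]:
            best = (float(r2[k]), (float(t[i]), float(t[j[k]])))
    return best[1]


@dataclasses.dataclass
class AssayMeasurement:
    """One background-subtracted fluorescence-intensity reading."""

    analyte: str
    sample_id: str
    time_h: float
    raw_fi: float
    background_fi: float
    net_fi: float
    below_detection: bool


def subtract_background(
    measurements: pd.DataFrame,
    background: dict[str, float],
    detection_floor: dict[str, float] | None = None,
) -> tuple[list[AssayMeasurement], list[str]]:
    """Background-subtract raw FI readings and flag sub-detection signals.

    Parameters
    ----------
    measurements:
        DataFrame with columns ``analyte, sample, time_h, fi``.
    background:
        Medium-only FI per analyte; every analyte present in
        ``measurements`` must have one.
    detection_floor:
        Per-analyte FI floor; defaults to
        :data:`DEFAULT_DETECTION_FLOORS` (0 for unlisted analytes).

    Returns
    -------
    (records, non_informative):
        All measurements with ``net = max(raw - background, 0)`` and a
        ``below_detection`` flag (net <= floor), plus the analytes whose
        every time point is flagged — treated as uninformative.
    """
    floors = dict(DEFAULT_DETECTION_FLOORS)
    if detection_floor:
        floors.update(detection_floor)
    required = {"analyte", "sample", "time_h", "fi"}
    missing = required - set(measurements.columns)
    if missing:
        raise DataError(f"FI table missing columns: {sorted(missing)}")
    records: list[AssayMeasurement] = []
    for _, row in measurements.iterrows():
        analyte = str(row["analyte"])
        if analyte not in background:
            raise DataError(f"no background FI for analyte {analyte!r}")
        raw = float(row["fi"])
        bg = float(background[analyte])
        net = max(raw - bg, 0.0)
        floor = float(floors.get(analyte, 0.0))
        records.append(AssayMeasurement(
            analyte=analyte, sample_id=str(row["sample"]),
            time_h=float(row["time_h"]), raw_fi=raw, background_fi=bg,
            net_fi=net, below_detection=net <= floor,
        ))
    non_informative = sorted({
        a for a in {r.analyte for r in records}
        if all(r.below_detection for r in records if r.analyte == a)
    })
    return records, non_informative
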