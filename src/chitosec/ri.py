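"""Refractive-index chromatogram handling.

The RI detector responds to mass concentration essentially independently of
chitosan DP and FA, so baseline-corrected peak areas are relative mass
measures.  This module loads exported RI traces (two-column CSV: time in
minutes, signal in microRIU, nominally 10 Hz), removes a slowly varying
baseline, detects and integrates peaks, and — central to the live-digestion
analysis — integrates fixed per-DP retention-time windows and splits the
trace into the small-oligomer (DP <= cutoff) and polymer/large-oligomer
fractions.

Fixed windows rather than per-peak matching are used for per-DP areas
because species of the same DP co-elute in this solvent system and windows
remain robust when neighbouring peaks shoulder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .errors import (
    ConfigurationError,
    FormatError,
    ParameterError,
    UndefinedShareError,
    ValidationError,
)


@dataclass
class Chromatogram:
    """Uniformly sampled RI trace: times in minutes, signal in microRIU."""

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValidationError("time and signal must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise ValidationError("chromatogram needs at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time axis must be strictly increasing")
        if dt.max() - dt.min() > 0.01 * dt.mean():
            raise ValidationError("time axis jitter exceeds 1% of sampling interval")

    @property
    def dt(self) -> float:
        """Sampling interval in minutes."""
        return float(np.mean(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


def load_ri_csv(path: str | Path, **metadata) -> Chromatogram:
    """Load an exported RI trace (header + two numeric columns: min, uRIU)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize parse failures
        raise FormatError(f"cannot parse RI CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"RI CSV {path} needs two columns, found {df.shape[1]}")
    try:
        t = df.iloc[:, 0].astype(float).to_numpy()
        s = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric data in RI CSV {path}") from exc
    if len(t) < 2:
        raise FormatError(f"RI CSV {path} has fewer than 2 rows")
    try:
        return Chromatogram(t, s, dict(metadata, path=str(path)))
    except ValidationError as exc:
        raise FormatError(f"RI CSV {path}: {exc}") from exc


def correct_baseline(
    c: Chromatogram, window: float = 12.0, smooth: float = 0.1
) -> Chromatogram:
    """Subtract a slowly varying baseline.

    The baseline is a rolling minimum over ``window`` minutes followed by a
    rolling mean over ``smooth`` minutes; both are deterministic and leave
    features narrower than ``window`` essentially untouched while removing
    constant offsets and slow drift.  The default window is deliberately
    almost as long as a whole run: mid-digestion the polymer band is a
    several-minute-wide hump, and a shorter rolling minimum would carve
    into it and bias the polymer area low.
    """
    if window <= 0:
        raise ParameterError(f"baseline window must be > 0, got {window}")
    span = c.time[-1] - c.time[0]
    if window > span:
        raise ParameterError(f"baseline window {window} min exceeds trace span {span:.3g} min")
    npts = max(int(round(window / c.dt)), 1)
    nsm = max(int(round(smooth / c.dt)), 1)
    # smooth before taking the minimum: a rolling minimum of raw noise sits
    # several sigma below the true baseline and would bias every area high
    base = uniform_filter1d(c.signal, size=nsm, mode="nearest")
    base = minimum_filter1d(base, size=npts, mode="nearest")
    base = uniform_filter1d(base, size=nsm, mode="nearest")
    return Chromatogram(c.time.copy(), c.signal - base, dict(c.metadata, baseline_corrected=True))


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak with trapezoidal area."""

    rt_start: float
    rt_apex: float
    rt_end: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if not (self.rt_start < self.rt_apex < self.rt_end):
            raise ValidationError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValidationError("peak area must be >= 0")


def detect_peaks(
    c: Chromatogram, min_height: float = 0.0, smooth_window: int = 5
) -> list[Peak]:
    """Detect peaks as local maxima of the smoothed trace above ``min_height``.

    Peak bounds are the flanking valley minima (or trace ends); areas are
    trapezoidal integrals of the unsmoothed signal between the bounds.
    Plateau apexes resolve to the earliest RT.
    """
    if min_height < 0:
        raise ParameterError("min_height must be >= 0")
    sig = uniform_filter1d(c.signal, size=max(smooth_window, 1)) if smooth_window > 1 else c.signal
    idx, _ = find_peaks(sig, height=min_height if min_height > 0 else None)
    if min_height == 0:
        idx = idx[sig[idx] > 0]
    if len(idx) == 0:
        return []
    peaks = []
    edges = [0, *[(a + int(np.argmin(sig[a:b + 1]))) for a, b in zip(idx[:-1], idx[1:])], len(c) - 1]
    for k, apex in enumerate(idx):
        lo, hi = edges[k], edges[k + 1]
        area = float(np.trapezoid(c.signal[lo:hi + 1], c.time[lo:hi + 1]))
        peaks.append(
            Peak(
                rt_start=float(c.time[lo]),
                rt_apex=float(c.time[apex]),
                rt_end=float(c.time[hi]),
                height=float(c.signal[apex]),
                area=max(area, 0.0),
            )
        )
    return peaks


class DPWindowMap:
    """Retention-time windows per oligomer DP, plus the polymer region.

    SEC elutes large analytes first, so windows are ordered by decreasing DP
    with increasing RT and must not overlap.  Windows are half-open
    ``[rt_lo, rt_hi)``.  The polymer region spans from the void time to the
    start of the largest-DP window and collects everything above the DP
    cutoff ("polymers and large oligomers").
    """

    def __init__(self, windows: Mapping[int, tuple[float, float]],
                 polymer_region: tuple[float, float]):
        items = sorted(windows.items(), key=lambda kv: kv[1][0])  # by rt_lo
        dps = [dp for dp, _ in items]
        if any(lo >= hi for _, (lo, hi) in items):
            raise ConfigurationError("each DP window needs rt_lo < rt_hi")
        for (_, (_, hi1)), (_, (lo2, _)) in zip(items[:-1], items[1:]):
            if hi1 > lo2:
                raise ConfigurationError("DP windows overlap")
        if dps != sorted(dps, reverse=True):
            raise ConfigurationError("DP must decrease with increasing RT (SEC order)")
        plo, phi = polymer_region
        if plo >= phi:
            raise ConfigurationError("polymer region needs rt_lo < rt_hi")
        self.windows = dict(items)
        self.polymer_region = (float(plo), float(phi))

    @property
    def dps(self) -> list[int]:
        return sorted(self.windows)

    def window_for(self, dp: int) -> tuple[float, float]:
        try:
            return self.windows[dp]
        except KeyError:
            raise ConfigurationError(f"DP {dp} not in window map") from None

    def dp_at(self, rt: float) -> int | None:
        """DP whose half-open window contains rt, or None."""
        for dp, (lo, hi) in self.windows.items():
            if lo <= rt < hi:
                return dp
        return None

    def to_csv(self, path: str | Path) -> None:
        rows = [{"dp": dp, "rt_lo": lo, "rt_hi": hi} for dp, (lo, hi) in self.windows.items()]
        rows.append({"dp": "polymer", "rt_lo": self.polymer_region[0],
                     "rt_hi": self.polymer_region[1]})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DPWindowMap":
        df = pd.read_csv(path)
        windows: dict[int, tuple[float, float]] = {}
        polymer = None
        for row in df.itertuples(index=False):
            if str(row.dp).strip().lower() == "polymer":
                polymer = (float(row.rt_lo), float(row.rt_hi))
            else:
                windows[int(row.dp)] = (float(row.rt_lo), float(row.rt_hi))
        if polymer is None:
            raise FormatError(f"window map {path} lacks the polymer region row")
        return cls(windows, polymer)


def windows_from_calibration(
    model,
    dp_min: int = 2,
    dp_max: int = 10,
    void_rt: float = 2.0,
    halfwidth_cap: float | None = None,
) -> DPWindowMap:
    """Construct a DP window map from a calibration model.

    Each DP is centred at the predicted RT of the fully deacetylated
    oligomer of that DP (species of one DP co-elute, so one nominal mass per
    DP suffices); window bounds sit midway between adjacent centres.  The
    polymer region runs from ``void_rt`` to the start of the DP ``dp_max``
    window.
    """
    from .chemistry import Composition, composition_mass

    dps = list(range(dp_max, dp_min - 1, -1))  # decreasing DP = increasing RT
    centers = [model.predict_rt(composition_mass(Composition(0, d)))[0] for d in dps]
    if any(b <= a for a, b in zip(centers[:-1], centers[1:])):
        raise ConfigurationError("calibration does not separate requested DPs")
    gaps = np.diff(centers)
    windows = {}
    for i, (dp, ctr) in enumerate(zip(dps, centers)):
        left = gaps[i - 1] / 2 if i > 0 else gaps[0] / 2
        right = gaps[i] / 2 if i < len(gaps) else gaps[-1] / 2
        if halfwidth_cap is not None:
            left, right = min(left, halfwidth_cap), min(right, halfwidth_cap)
        windows[dp] = (ctr - left, ctr + right)
    polymer = (void_rt, windows[dp_max][0])
    return DPWindowMap(windows, polymer)


def windows_from_ladder(
    c: Chromatogram,
    dp_max: int,
    min_height: float = 0.0,
    void_rt: float = 2.0,
) -> DPWindowMap:
    """Derive a window map from a reference oligomer-ladder run.

    Detected peaks are assigned DPs in decreasing order with increasing RT,
    starting at ``dp_max``; bounds sit midway between adjacent apexes.
    """
    peaks = detect_peaks(c, min_height=min_height)
    peaks = [p for p in peaks if p.rt_apex > void_rt]
    if not peaks:
        raise ConfigurationError("no peaks found in ladder run")
    centers = sorted(p.rt_apex for p in peaks)
    dps = list(range(dp_max, dp_max - len(centers), -1))
    if dps[-1] < 1:
        raise ConfigurationError("more ladder peaks than available DP labels")
    gaps = np.diff(centers) if len(centers) > 1 else np.array([0.2])
    windows = {}
    for i, (dp, ctr) in enumerate(zip(dps, centers)):
        left = gaps[i - 1] / 2 if i > 0 else gaps[0] / 2
        right = gaps[i] / 2 if i < len(gaps) else gaps[-1] / 2
        windows[dp] = (ctr - left, ctr + right)
    return DPWindowMap(windows, (void_rt, windows[dp_max][0]))


def _window_area(c: Chromatogram, lo: float, hi: float) -> float:
    mask = (c.time >= lo) & (c.time < hi)
    if mask.sum() < 2:
        return 0.0
    return max(float(np.trapezoid(c.signal[mask], c.time[mask])), 0.0)


def integrate_windows(c: Chromatogram, w: DPWindowMap) -> dict[int, float]:
    """Trapezoidal area (uRIU*min, clipped at 0) of each DP window."""
    return {dp: _window_area(c, lo, hi) for dp, (lo, hi) in w.windows.items()}


def integrate_polymer(c: Chromatogram, w: DPWindowMap) -> float:
    """Area of the polymer / large-oligomer region."""
    return _window_area(c, *w.polymer_region)


def split_fractions(
    dp_areas: Mapping[int, float], polymer_area: float
) -> tuple[float, float]:
    """Normalize to (small-oligomer share, polymer share); they sum to 1."""
    if polymer_area < 0 or any(a < 0 for a in dp_areas.values()):
        raise ValidationError("areas must be >= 0")
    small = float(sum(dp_areas.values()))
    total = small + float(polymer_area)
    if total <= 0:
        raise UndefinedShareError("all areas are zero; shares undefined")
    return small / total, polymer_area / total
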