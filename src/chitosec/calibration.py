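"""Segmented exponential molecular-weight vs retention-time calibration for SEC.

In size-exclusion chromatography larger analytes elute earlier.  Over a
limited mass range the relation between molar mass M and retention time RT
is well described by an exponential, i.e. a straight line in
``ln(M) = a + b * RT`` with b < 0.  A single line does not span the whole
usable range of the column, so the calibration is segmented: by default the
low (0.1-1 kDa), medium (1-10 kDa) and high (10-1000 kDa) mass ranges each
get their own ordinary-least-squares fit.

A fitted :class:`CalibrationModel` converts RT to mass (``predict_mass``)
and mass to RT (``predict_rt``), turns an RI chromatogram region into a
mass distribution, and reports the peak-maximum molecular weight used to
track polymer degradation over a digestion.  The same machinery serves the
weight-average (Mw) and number-average (Mn) statistic; the model records
which one it maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import FitError, NoPeakError, ValidationError

DEFAULT_SEGMENT_BOUNDS: tuple[tuple[float, float], ...] = (
    (100.0, 1_000.0),
    (1_000.0, 10_000.0),
    (10_000.0, 1_000_000.0),
)


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: a sample of known Mw/Mn and its RI-peak-maximum RT.

    ``source`` records where the mass value came from (SEC-MALS-RI for
    polymers, m/z-derived for oligomers, or supplier data).
    """

    sample_id: str
    mw_da: float
    mn_da: float | None
    rt_min: float
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.mw_da <= 0 or self.rt_min <= 0:
            raise ValidationError(f"standard {self.sample_id}: Mw and RT must be > 0")
        if self.mn_da is not None and not (self.mw_da >= self.mn_da > 0):
            raise ValidationError(f"standard {self.sample_id}: need Mw >= Mn > 0")

    def mass(self, statistic: str) -> float:
        if statistic == "Mw":
            return self.mw_da
        if statistic == "Mn":
            if self.mn_da is None:
                raise ValidationError(f"standard {self.sample_id} has no Mn value")
            return self.mn_da
        raise ValidationError(f"unknown statistic: {statistic!r}")


def load_standards_csv(path: str | Path) -> list[CalibrationStandard]:
    """Read standards from CSV with columns id,mw_da,mn_da,rt_min,source."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        mn = getattr(row, "mn_da", None)
        mn = None if mn is None or pd.isna(mn) else float(mn)
        out.append(
            CalibrationStandard(
                str(row.id), float(row.mw_da), mn, float(row.rt_min),
                str(getattr(row, "source", "unknown")),
            )
        )
    return out


@dataclass(frozen=True)
class Segment:
    """One fitted ln(M) = a + b*RT line with its validity ranges."""

    mass_lo: float
    mass_hi: float
    rt_lo: float
    rt_hi: float
    intercept: float
    slope: float
    r2: float
    n: int = 0

    def mass_at(self, rt: float) -> float:
        return float(np.exp(self.intercept + self.slope * rt))

    def rt_at(self, mass: float) -> float:
        return float((np.log(mass) - self.intercept) / self.slope)


class CalibrationModel:
    """Ordered piecewise-exponential mass-RT calibration.

    Segments are kept sorted by decreasing mass (increasing RT).  Each
    segment must have negative slope: mass decreases with retention time.
    """

    def __init__(self, statistic: str, segments: Sequence[Segment]):
        if statistic not in ("Mw", "Mn"):
            raise ValidationError(f"statistic must be 'Mw' or 'Mn', got {statistic!r}")
        if not segments:
            raise ValidationError("calibration model needs at least one segment")
        for s in segments:
            if s.slope >= 0:
                raise ValidationError(
                    f"segment {s.mass_lo:g}-{s.mass_hi:g} Da has non-negative slope"
                )
        self.statistic = statistic
        self.segments = sorted(segments, key=lambda s: -s.mass_hi)

    # --- segment selection -------------------------------------------------
    def _segment_for_rt(self, rt: float) -> tuple[Segment, bool]:
        """Segment whose fitted RT range contains rt; at a shared boundary the
        later-RT (lower-mass) segment wins.  Outside all ranges: nearest."""
        for s in reversed(self.segments):  # low-mass (late-RT) first
            if s.rt_lo <= rt <= s.rt_hi:
                return s, False
        # nearest segment by RT distance
        def dist(s: Segment) -> float:
            return min(abs(rt - s.rt_lo), abs(rt - s.rt_hi))
        return min(self.segments, key=dist), True

    def _segment_for_mass(self, mass: float) -> tuple[Segment, bool]:
        """Segment whose mass range contains mass; on a bound the lower-mass
        segment wins (a standard sitting on a bound belongs to it too)."""
        for s in reversed(self.segments):  # lower-mass segments first
            if s.mass_lo <= mass <= s.mass_hi:
                return s, False
        def dist(s: Segment) -> float:
            return min(abs(np.log(mass) - np.log(s.mass_lo)),
                       abs(np.log(mass) - np.log(s.mass_hi)))
        return min(self.segments, key=dist), True

    # --- prediction --------------------------------------------------------
    def predict_mass(self, rt: float) -> tuple[float, bool]:
        """Mass (Da) at a retention time; flag True when extrapolating."""
        if rt <= 0:
            raise ValidationError(f"rt must be > 0, got {rt}")
        seg, extrap = self._segment_for_rt(rt)
        return seg.mass_at(rt), extrap

    def predict_rt(self, mass: float) -> tuple[float, bool]:
        """Retention time (min) at a mass; flag True when extrapolating."""
        if mass <= 0:
            raise ValidationError(f"mass must be > 0, got {mass}")
        seg, extrap = self._segment_for_mass(mass)
        return seg.rt_at(mass), extrap

    # --- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "statistic": self.statistic,
            "segments": [vars(s) for s in self.segments],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        segs = [Segment(**s) for s in payload["segments"]]
        return cls(payload["statistic"], segs)


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    segment_bounds: Sequence[tuple[float, float]] = DEFAULT_SEGMENT_BOUNDS,
    statistic: str = "Mw",
) -> CalibrationModel:
    """Fit one OLS line of ln(M) on RT per mass segment.

    A standard whose mass sits exactly on a segment bound is assigned to the
    lower-mass segment.  Every segment needs at least two standards.
    """
    segments = []
    bounds = sorted(segment_bounds, key=lambda b: b[0])
    for i, (lo, hi) in enumerate(bounds):
        sel = []
        for st in standards:
            m = st.mass(statistic)
            # boundary masses belong to the lower-mass segment: (lo, hi] here,
            # with lo itself included only in the lowest segment
            if (lo < m <= hi) or (i == 0 and m == lo):
                sel.append(st)
        if len(sel) < 2:
            raise FitError(
                f"segment {lo:g}-{hi:g} Da has {len(sel)} standard(s); need >= 2"
            )
        rt = np.array([s.rt_min for s in sel])
        lnm = np.log([s.mass(statistic) for s in sel])
        slope, intercept = np.polyfit(rt, lnm, 1)
        pred = intercept + slope * rt
        ss_res = float(np.sum((lnm - pred) ** 2))
        ss_tot = float(np.sum((lnm - lnm.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        segments.append(
            Segment(lo, hi, float(rt.min()), float(rt.max()),
                    float(intercept), float(slope), r2, len(sel))
        )
    return CalibrationModel(statistic, segments)


def mw_distribution(
    model: CalibrationModel,
    chrom,
    region: tuple[float, float],
) -> pd.DataFrame:
    """Map each chromatogram sample in ``region`` (rt_lo, rt_hi) to a mass.

    Returns a DataFrame with columns ``mw_da, riu``; mass decreases along
    the trace while the RI signal is carried over unchanged.  This is the
    second-x-axis view of the polymer peak.
    """
    lo, hi = region
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    times = chrom.time[mask]
    masses = np.array([model.predict_mass(t)[0] for t in times])
    return pd.DataFrame({"mw_da": masses, "riu": chrom.signal[mask]})


def peak_max_mw(
    model: CalibrationModel,
    chrom,
    region: tuple[float, float],
    smooth_window: int = 7,
) -> tuple[float, bool]:
    """Molecular weight at the RI-signal peak maximum within a region.

    The sample RT is defined as the RT of the RI peak maximum of the
    (lightly smoothed) trace; ties go to the earlier RT.  Raises
    :class:`NoPeakError` when the region holds no positive signal.
    """
    lo, hi = region
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    if not mask.any():
        raise NoPeakError(f"empty region {lo}-{hi} min")
    sig = chrom.signal[mask]
    if smooth_window > 1:
        sig = uniform_filter1d(sig, size=smooth_window)
    if np.all(sig <= 0):
        raise NoPeakError(f"no positive RI signal in region {lo}-{hi} min")
    rt_apex = float(chrom.time[mask][int(np.argmax(sig))])
    return model.predict_mass(rt_apex)


def dispersity(mw: float, mn: float) -> float:
    """Dispersity DM = Mw / Mn (>= 1 for any real distribution)."""
    if mn <= 0:
        raise ValidationError(f"Mn must be > 0, got {mn}")
    if mw < mn:
        raise ValidationError(f"Mw ({mw}) < Mn ({mn}) violates dispersity >= 1")
    return mw / mn
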