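"""RI/MS signal fusion into per-(DP, FA) weight fractions and time courses.

Semi-quantitative oligomer analysis rests on three properties of the
setup: species of one DP co-elute in a single RI peak; the RI response
depends only on mass concentration; and ionization efficiency is similar
within one DP (though very different between DPs, peaking at DP 3).
Consequently the RI area of a DP window measures the mass of that DP
relative to the other DPs, and the MS intensity ratios *within* one DP
measure the mass ratios of its species.  The product of the two is the
weight fraction of each (DP, FA) species in the small-oligomer pool;
multiplying by the pool's share of the injected mass gives micrograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chemistry import Composition, composition_mass
from .errors import UndefinedFAError, ValidationError

def combine_ri_ms(
    dp_areas: Mapping[int, float],
    intensities: Mapping[Composition, float],
    cutoff_dp: int = 10,
) -> dict:
    """Fuse per-DP RI areas with within-DP MS intensity ratios.

    Weight fraction of species s of DP d in the DP <= cutoff pool:
    ``area(d) / sum(areas) * intensity(s) / sum(intensities of DP d)``.
    Within-DP intensity ratios are read as mass ratios.  A DP with RI area
    but zero total MS intensity contributes an ``"DP{d}_unassigned"``
    record carrying that DP's whole share — a visible RI/MS inconsistency,
    never silently dropped.  Returns an empty dict when the pool is empty.
    """
    areas = {int(d): float(a) for d, a in dp_areas.items() if int(d) <= cutoff_dp}
    if any(a < 0 for a in areas.values()):
        raise ValidationError("negative RI area")
    if any(v < 0 for v in intensities.values()):
        raise ValidationError("negative MS intensity")
    total = sum(areas.values())
    if total <= 0:
        return {}
    by_dp: dict[int, float] = {}
    for comp, v in intensities.items():
        by_dp[comp.dp] = by_dp.get(comp.dp, 0.0) + float(v)
    out: dict = {}
    for d, a in areas.items():
        if a == 0:
            continue
        dp_share = a / total
        if by_dp.get(d, 0.0) > 0:
            for comp, v in intensities.items():
                if comp.dp == d and v > 0:
                    out[comp] = dp_share * float(v) / by_dp[d]
        else:
            out[f"DP{d}_unassigned"] = dp_share
    return out


def absolute_amounts(
    fractions: Mapping, small_share: float, injected_ug: float
) -> dict:
    """Micrograms per species: fraction x small-oligomer share x injected mass."""
    if not 0.0 <= small_share <= 1.0:
        raise ValidationError(f"small-oligomer share must be in [0, 1], got {small_share}")
    if injected_ug <= 0:
        raise ValidationError(f"injected mass must be > 0, got {injected_ug}")
    return {k: f * small_share * injected_ug for k, f in fractions.items()}


def average_fa(
    amounts: Mapping, mode: str = "molar", monoisotopic: bool = True
) -> float:
    """Average FA of the product pool from per-species amounts.

    ``molar`` (default): moles(s) = amount / mass(s); FA is the fraction of
    A among all monomer units, sum(moles * nA) / sum(moles * DP).
    ``weight``: amount-weighted mean of the per-species FA values.
    Unassigned (non-composition) records have unknown FA and are excluded.
    """
    if mode not in ("molar", "weight"):
        raise ValidationError(f"fa mode must be 'molar' or 'weight', got {mode!r}")
    comps = {k: v for k, v in amounts.items() if isinstance(k, Composition)}
    total = sum(comps.values())
    if total <= 0:
        raise UndefinedFAError("empty or zero-amount pool has no average FA")
    if mode == "weight":
        return sum(v * c.fa for c, v in comps.items()) / total
    num = den = 0.0
    for c, v in comps.items():
        moles = v / composition_mass(c, monoisotopic)
        num += moles * c.nA
        den += moles * c.dp
    return num / den


@dataclass(frozen=True)
class OligomerQuantRecord:
    """One (timepoint, species) quantification row."""

    timepoint_min: float
    composition: Composition | None  # None for an unassigned-DP remainder
    label: str
    dp: int
    ms_intensity: float
    dp_area: float
    weight_fraction: float
    amount_ug: float

    @property
    def fa(self) -> float | None:
        return self.composition.fa if self.composition is not None else None


@dataclass(frozen=True)
class TimepointResult:
    """All derived quantities of one injection."""

    time_min: float
    polymer_peak_mw_da: float  # NaN when no polymer peak
    extrapolated: bool
    small_oligomer_share: float
    small_oligomer_ug: float
    avg_fa: float  # NaN for an empty pool
    records: tuple[OligomerQuantRecord, ...] = ()


@dataclass
class TimeCourse:
    """Ordered per-timepoint results of one live digestion."""

    timepoints: list[TimepointResult] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.timepoints)

    def __iter__(self):
        return iter(self.timepoints)

    @property
    def times(self) -> list[float]:
        return [tp.time_min for tp in self.timepoints]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint_min": self.times,
                "polymer_peak_mw_da": [tp.polymer_peak_mw_da for tp in self.timepoints],
                "extrapolated": [tp.extrapolated for tp in self.timepoints],
                "small_oligomer_share": [tp.small_oligomer_share for tp in self.timepoints],
                "small_oligomer_ug": [tp.small_oligomer_ug for tp in self.timepoints],
                "avg_fa": [tp.avg_fa for tp in self.timepoints],
            }
        )

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for tp in self.timepoints:
            for r in tp.records:
                rows.append(
                    {
                        "timepoint_min": r.timepoint_min,
                        "label": r.label,
                        "nA": r.composition.nA if r.composition else None,
                        "nD": r.composition.nD if r.composition else None,
                        "dp": r.dp,
                        "fa": r.fa,
                        "ms_intensity": r.ms_intensity,
                        "dp_area": r.dp_area,
                        "weight_fraction": r.weight_fraction,
                        "amount_ug": r.amount_ug,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["timepoint_min", "label", "nA", "nD", "dp", "fa",
                     "ms_intensity", "dp_area", "weight_fraction", "amount_ug"],
        )


def assemble_timecourse(results: Sequence[TimepointResult]) -> TimeCourse:
    """Sort per-timepoint results into a TimeCourse; duplicate times are an error."""
    if not results:
        raise ValidationError("timecourse needs at least one timepoint")
    times = [r.time_min for r in results]
    if len(set(times)) != len(times):
        raise ValidationError("duplicate timepoints in timecourse input")
    return TimeCourse(sorted(results, key=lambda r: r.time_min))


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return "nan" if math.isnan(x) else f"{x:.6g}"
    return str(x)


_CSV_COLUMNS = [
    "timepoint_min", "row_type", "label", "nA", "nD", "dp", "fa",
    "ms_intensity", "dp_area", "weight_fraction", "amount_ug",
    "polymer_peak_mw_da", "extrapolated", "small_oligomer_share",
    "small_oligomer_ug", "avg_fa",
]


def export_combined_csv(tc: TimeCourse, path: str | Path) -> None:
    """Write the final combined CSV: one row per (timepoint, species) plus a
    summary row per timepoint.  Floats are fixed to 6 significant digits so
    re-running on identical inputs is byte-identical."""
    if not len(tc):
        raise ValidationError("cannot export an empty timecourse")
    lines = [",".join(_CSV_COLUMNS)]
    for tp in tc:
        for r in tp.records:
            vals = [_fmt(r.timepoint_min), "oligomer", r.label,
                    _fmt(r.composition.nA if r.composition else None),
                    _fmt(r.composition.nD if r.composition else None),
                    _fmt(r.dp), _fmt(r.fa), _fmt(r.ms_intensity), _fmt(r.dp_area),
                    _fmt(r.weight_fraction), _fmt(r.amount_ug), "", "", "", "", ""]
            lines.append(",".join(vals))
        vals = [_fmt(tp.time_min), "summary", "", "", "", "", "", "", "", "", "",
                _fmt(tp.polymer_peak_mw_da), _fmt(tp.extrapolated),
                _fmt(tp.small_oligomer_share), _fmt(tp.small_oligomer_ug),
                _fmt(tp.avg_fa)]
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_combined_csv(path: str | Path) -> TimeCourse:
    """Re-import a combined CSV written by :func:`export_combined_csv`."""
    df = pd.read_csv(path)
    results = []
    for t, grp in df.groupby("timepoint_min", sort=True):
        records = []
        for row in grp[grp["row_type"] == "oligomer"].itertuples(index=False):
            comp = (Composition(int(row.nA), int(row.nD))
                    if pd.notna(row.nA) and pd.notna(row.nD) else None)
            records.append(
                OligomerQuantRecord(
                    timepoint_min=float(t), composition=comp, label=str(row.label),
                    dp=int(row.dp), ms_intensity=float(row.ms_intensity),
                    dp_area=float(row.dp_area),
                    weight_fraction=float(row.weight_fraction),
                    amount_ug=float(row.amount_ug),
                )
            )
        summ = grp[grp["row_type"] == "summary"]
        if len(summ) != 1:
            raise ValidationError(f"timepoint {t}: expected exactly one summary row")
        s = summ.iloc[0]
        results.append(
            TimepointResult(
                time_min=float(t),
                polymer_peak_mw_da=float(s["polymer_peak_mw_da"]),
                extrapolated=bool(s["extrapolated"]),
                small_oligomer_share=float(s["small_oligomer_share"]),
                small_oligomer_ug=float(s["small_oligomer_ug"]),
                avg_fa=float(s["avg_fa"]),
                records=tuple(records),
            )
        )
    return assemble_timecourse(results)
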