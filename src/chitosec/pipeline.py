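"""End-to-end live-digestion analysis driven by a run manifest.

One manifest describes one live digestion: an ordered list of timepoints,
each with an RI chromatogram CSV and an mzML run, plus the calibration
model, DP window map, candidate table, injected mass and options.  The
pipeline executes load -> baseline correction -> window integration ->
MS harvest -> RI/MS fusion -> time-course assembly -> export, logging
record counts per stage.  Outputs are deterministic given the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationModel, peak_max_mw
from .chemistry import CandidateTable
from .errors import ChitosecError, NoPeakError, UndefinedShareError, ValidationError
from .ms import harvest_intensities, load_ms_run
from .quantify import (
    TimeCourse,
    TimepointResult,
    OligomerQuantRecord,
    absolute_amounts,
    assemble_timecourse,
    average_fa,
    combine_ri_ms,
    export_combined_csv,
)
from .ri import (
    DPWindowMap,
    correct_baseline,
    integrate_polymer,
    integrate_windows,
    load_ri_csv,
    split_fractions,
)

log = logging.getLogger("chitosec")


@dataclass
class RunEntry:
    time_min: float
    ri_csv: Path
    mzml: Path


@dataclass
class RunManifest:
    """Validated description of one live-digestion dataset."""

    runs: list[RunEntry]
    calibration: Path
    windows: Path
    candidates: Path
    injected_ug: float = 3.0
    cutoff_dp: int = 10
    mz_tol: float = 0.3
    rt_offset: float = 0.0
    fa_mode: str = "molar"
    baseline_window: float = 12.0
    baseline_smooth: float = 0.1
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValidationError("manifest lists no runs")
        times = [r.time_min for r in self.runs]
        if any(b <= a for a, b in zip(times[:-1], times[1:])):
            raise ValidationError("manifest timepoints must be unique and increasing")
        if self.injected_ug <= 0:
            raise ValidationError("injected_ug must be > 0")
        missing = [
            str(p)
            for p in [self.calibration, self.windows, self.candidates,
                      *(r.ri_csv for r in self.runs), *(r.mzml for r in self.runs)]
            if not Path(p).is_file()
        ]
        if missing:
            raise ValidationError(f"manifest references missing files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            runs = [
                RunEntry(float(e["time_min"]), resolve(e["ri_csv"]), resolve(e["mzml"]))
                for e in data["runs"]
            ]
            known = {"runs", "calibration", "windows", "candidates", "injected_ug",
                     "cutoff_dp", "mz_tol", "rt_offset", "fa_mode",
                     "baseline_window", "baseline_smooth"}
            return cls(
                runs=sorted(runs, key=lambda r: r.time_min),
                calibration=resolve(data["calibration"]),
                windows=resolve(data["windows"]),
                candidates=resolve(data["candidates"]),
                injected_ug=float(data.get("injected_ug", 3.0)),
                cutoff_dp=int(data.get("cutoff_dp", 10)),
                mz_tol=float(data.get("mz_tol", 0.3)),
                rt_offset=float(data.get("rt_offset", 0.0)),
                fa_mode=str(data.get("fa_mode", "molar")),
                baseline_window=float(data.get("baseline_window", 12.0)),
                baseline_smooth=float(data.get("baseline_smooth", 0.1)),
                extra={k: v for k, v in data.items() if k not in known},
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed manifest {path}: {exc}") from exc


def analyze_timepoint(
    entry: RunEntry,
    model: CalibrationModel,
    windows: DPWindowMap,
    candidates: CandidateTable,
    manifest: RunManifest,
) -> TimepointResult:
    """Run the full single-injection analysis for one timepoint."""
    chrom = load_ri_csv(entry.ri_csv, time_min=entry.time_min)
    corrected = correct_baseline(chrom, manifest.baseline_window, manifest.baseline_smooth)
    dp_areas = integrate_windows(corrected, windows)
    polymer_area = integrate_polymer(corrected, windows)
    try:
        small_share, _ = split_fractions(dp_areas, polymer_area)
    except UndefinedShareError:
        raise ChitosecError(
            f"t={entry.time_min} min: no RI signal in any window; cannot split fractions"
        ) from None
    try:
        mw, extrapolated = peak_max_mw(model, corrected, windows.polymer_region)
    except NoPeakError:
        log.warning("t=%g min: no polymer peak; reporting NaN Mw", entry.time_min)
        mw, extrapolated = float("nan"), False

    series = load_ms_run(entry.mzml)
    intensities = harvest_intensities(
        series, candidates, windows, tol=manifest.mz_tol, rt_offset=manifest.rt_offset
    )
    fractions = combine_ri_ms(dp_areas, intensities, manifest.cutoff_dp)
    amounts = absolute_amounts(fractions, small_share, manifest.injected_ug)
    try:
        fa = average_fa(amounts, mode=manifest.fa_mode)
    except ChitosecError:
        fa = float("nan")

    records = []
    for key in sorted(fractions, key=lambda k: (isinstance(k, str), str(k))):
        comp = None if isinstance(key, str) else key
        dp = int(key.removeprefix("DP").removesuffix("_unassigned")) if comp is None else comp.dp
        records.append(
            OligomerQuantRecord(
                timepoint_min=entry.time_min,
                composition=comp,
                label=key if comp is None else comp.label,
                dp=dp,
                ms_intensity=0.0 if comp is None else intensities.get(comp, 0.0),
                dp_area=dp_areas.get(dp, 0.0),
                weight_fraction=fractions[key],
                amount_ug=amounts[key],
            )
        )
    log.info(
        "t=%g min: %d scans, %d species, small-oligomer share %.3f, peak Mw %.3g Da",
        entry.time_min, len(series), len(records), small_share, mw,
    )
    return TimepointResult(
        time_min=entry.time_min,
        polymer_peak_mw_da=mw,
        extrapolated=extrapolated,
        small_oligomer_share=small_share,
        small_oligomer_ug=small_share * manifest.injected_ug,
        avg_fa=fa,
        records=tuple(records),
    )


def run_analysis(manifest: RunManifest, out_dir: str | Path | None = None) -> TimeCourse:
    """Execute the whole pipeline for a manifest; optionally write reports.

    Any stage error aborts with the stage and timepoint named; partially
    written outputs are removed.
    """
    log.info("loading calibration %s", manifest.calibration)
    model = CalibrationModel.from_json(manifest.calibration)
    windows = DPWindowMap.from_csv(manifest.windows)
    candidates = CandidateTable.from_csv(manifest.candidates)
    log.info("windows: DP %s; candidates: %d rows", windows.dps, len(candidates))

    results = []
    for entry in manifest.runs:
        try:
            results.append(analyze_timepoint(entry, model, windows, candidates, manifest))
        except ChitosecError as exc:
            raise type(exc)(f"timepoint t={entry.time_min} min: {exc}") from exc
    tc = assemble_timecourse(results)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        combined = out / "combined.csv"
        tmp = combined.with_suffix(".csv.tmp")
        try:
            export_combined_csv(tc, tmp)
            tmp.replace(combined)
        finally:
            tmp.unlink(missing_ok=True)
        log.info("wrote %s (%d timepoints)", combined, len(tc))
    return tc
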