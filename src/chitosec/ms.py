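"""Mass-spectrometry run handling: mzML I/O and candidate-intensity harvest.

The MS side of the method yields one arbitrary intensity per candidate
oligomer composition per injection: for every candidate (composition,
adduct, theoretical m/z), centroids within an m/z tolerance are summed over
all scans whose retention time falls inside the composition's DP elution
window, and the adduct sums are added per composition.  Intensities are
arbitrary units; only within-DP ratios are interpreted downstream.

mzML I/O is self-contained: the writer emits plain centroided mzML with
uncompressed 64-bit base64 binary arrays, and the reader (stdlib XML)
handles 32/64-bit floats, zlib or uncompressed encoding, and RT in
minutes or seconds — the subset of the standard that centroided MS1
survey runs use.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

from .chemistry import CandidateTable, Composition
from .errors import ConfigurationError, FormatError, ValidationError
from .ri import DPWindowMap


@dataclass
class Scan:
    """One centroided MS1 scan."""

    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt_min = float(self.rt_min)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValidationError("negative centroid intensity")


@dataclass
class SpectrumSeries:
    """An ordered series of centroided scans from one injection."""

    scans: list[Scan] = field(default_factory=list)
    polarity: str = "positive"
    scan_range: tuple[float, float] = (50.0, 2000.0)

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.scans]
        if any(b < a for a, b in zip(rts[:-1], rts[1:])):
            raise ValidationError("scan retention times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.scans)


def _encode(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="chitosec" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="chitosec"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="chitosec">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
"""


def write_mzml(series: SpectrumSeries, path: str | Path) -> None:
    """Serialize a centroided series as plain (non-indexed) mzML 1.1.0.

    Binary arrays are uncompressed little-endian 64-bit floats, so a
    write -> read round trip is bit-exact.
    """
    pol_acc = ("MS:1000130", "positive scan") if series.polarity == "positive" \
        else ("MS:1000129", "negative scan")
    parts = [_MZML_HEADER]
    parts.append(f'  <run id="{escape(Path(path).stem)}" '
                 f'defaultInstrumentConfigurationRef="IC1">\n')
    parts.append(f'    <spectrumList count="{len(series)}" defaultDataProcessingRef="DP1">\n')
    for i, scan in enumerate(series.scans):
        n = len(scan.mz)
        mz_b64, int_b64 = _encode(scan.mz), _encode(scan.intensity)
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            f'        <cvParam cvRef="MS" accession="{pol_acc[0]}" name="{pol_acc[1]}" value=""/>\n'
            f'        <scanList count="1">\n'
            f'          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
            f'          <scan>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt_min!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            f'          </scan>\n'
            f'        </scanList>\n'
            f'        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
            f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            f'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f'            <binary>{mz_b64}</binary>\n'
            f'          </binaryDataArray>\n'
            f'          <binaryDataArray encodedLength="{len(int_b64)}">\n'
            f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            f'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
            f'            <binary>{int_b64}</binary>\n'
            f'          </binaryDataArray>\n'
            f'        </binaryDataArrayList>\n'
            f'      </spectrum>\n'
        )
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(parts))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ElementTree.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    dtype = "<f8"
    compressed = False
    kind = None
    b64 = ""
    for el in bda.iter():
        name = _local(el.tag)
        if name == "cvParam":
            acc = el.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            b64 = el.text or ""
    raw = base64.b64decode(b64)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def load_ms_run(path: str | Path, allow_profile: bool = False) -> SpectrumSeries:
    """Read an mzML file into a :class:`SpectrumSeries` (MS1 scans only).

    Retention times are normalized to minutes.  Profile spectra raise a
    :class:`FormatError` unless ``allow_profile`` is set (they are then taken
    as-is; no centroiding is attempted).
    """
    try:
        tree = ElementTree.parse(str(path))
    except ElementTree.ParseError as exc:
        raise FormatError(f"cannot parse mzML {path}: {exc}") from exc
    scans: list[Scan] = []
    for spec in tree.iter():
        if _local(spec.tag) != "spectrum":
            continue
        ms_level = 1
        profile = False
        rt_min: float | None = None
        arrays: dict[str, np.ndarray] = {}
        for el in spec.iter():
            name = _local(el.tag)
            if name == "cvParam":
                acc = el.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(el.get("value", "1"))
                elif acc == "MS:1000128":
                    profile = True
                elif acc == "MS:1000016":
                    unit = el.get("unitName", "minute")
                    rt = float(el.get("value", "nan"))
                    rt_min = rt / 60.0 if unit == "second" else rt
            elif name == "binaryDataArray":
                kind, values = _decode_binary_array(el)
                if kind is not None:
                    arrays[kind] = values
        if ms_level != 1:
            continue
        if profile and not allow_profile:
            raise FormatError(f"{path}: profile data; centroided scans required")
        if rt_min is None:
            raise FormatError(f"{path}: scan lacks retention-time metadata")
        if "mz" not in arrays or "intensity" not in arrays:
            raise FormatError(f"{path}: scan lacks m/z or intensity arrays")
        scans.append(Scan(rt_min, arrays["mz"], arrays["intensity"]))
    try:
        return SpectrumSeries(scans=scans)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def harvest_intensities(
    series: SpectrumSeries,
    candidates: CandidateTable,
    windows: DPWindowMap,
    tol: float = 0.3,
    rt_offset: float = 0.0,
) -> dict[Composition, float]:
    """One arbitrary intensity per candidate composition for this injection.

    For each composition, centroid intensities within ``tol`` Da/charge of
    each of its adduct m/z values are summed over every scan whose
    (RT + rt_offset) lies in the composition's DP window; adduct sums are
    then added.  ``rt_offset`` models the RI-vs-MS flow-path difference
    after the splitter.  A centroid falling inside several candidates'
    tolerance windows is assigned to the nearest theoretical m/z; exact
    ties are split equally.  Every candidate composition appears in the
    output (zero allowed).
    """
    if tol <= 0:
        raise ConfigurationError(f"m/z tolerance must be > 0, got {tol}")
    df = candidates.df
    for comp in candidates.compositions:
        if comp.dp not in windows.windows:
            raise ConfigurationError(f"DP {comp.dp} of candidate {comp.label} "
                                     f"missing from window map")
    out: dict[Composition, float] = {c: 0.0 for c in candidates.compositions}
    if not len(series):
        return out

    # group candidate rows by DP once
    by_dp: dict[int, tuple[np.ndarray, list[Composition]]] = {}
    for dp, grp in df.groupby(df["nA"] + df["nD"]):
        comps = [Composition(int(a), int(d)) for a, d in zip(grp["nA"], grp["nD"])]
        by_dp[int(dp)] = (grp["mz"].to_numpy(float), comps)

    for scan in series.scans:
        dp = windows.dp_at(scan.rt_min + rt_offset)
        if dp is None or dp not in by_dp:
            continue
        cand_mz, comps = by_dp[dp]
        if len(scan.mz) == 0:
            continue
        # distance matrix centroids x candidate rows
        dist = np.abs(scan.mz[:, None] - cand_mz[None, :])
        within = dist <= tol
        for ci in range(len(scan.mz)):
            hits = np.flatnonzero(within[ci])
            if hits.size == 0:
                continue
            d = dist[ci, hits]
            nearest = hits[d == d.min()]
            share = float(scan.intensity[ci]) / len(nearest)
            for j in nearest:
                out[comps[j]] += share
    return out
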