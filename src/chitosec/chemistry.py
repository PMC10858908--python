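"""Chitosan oligomer compositions, masses, adduct m/z values and candidate tables.

Chitosans are linear beta-1,4 copolymers of N-acetylglucosamine (GlcNAc,
"A" units) and glucosamine (GlcN, "D" units).  An oligomer composition is
fully described by the unit counts (nA, nD); the degree of polymerization is
DP = nA + nD and the fraction of acetylation FA = nA / DP.  Within one
(DP, FA) the acetylation pattern (PA) is not resolved by this method.

Neutral masses are residue-additive: nA * m(GlcNAc residue, C8H13NO5)
+ nD * m(GlcN residue, C6H11NO4) + m(H2O) for the terminal water.
Monoisotopic masses are the package default; average masses are available
for cross-checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

# Monoisotopic atomic masses (Da)
_MONO = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196}
# IUPAC 2021 standard atomic weights (Da)
_AVG = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999}

PROTON_MASS = 1.00727646688  # Da, H+ (H atom minus electron)
_ELECTRON_MASS = 0.000548579909
SODIUM_CATION_MASS = 22.9897692820 - _ELECTRON_MASS  # Da, Na+

# residue formulas: GlcNAc residue C8H13NO5, GlcN residue C6H11NO4, + H2O per chain
_A_RESIDUE = {"C": 8, "H": 13, "N": 1, "O": 5}
_D_RESIDUE = {"C": 6, "H": 11, "N": 1, "O": 4}
_WATER = {"C": 0, "H": 2, "N": 0, "O": 1}


def _formula_mass(counts: Mapping[str, int], table: Mapping[str, float]) -> float:
    return sum(n * table[el] for el, n in counts.items())


A_RESIDUE_MONO = _formula_mass(_A_RESIDUE, _MONO)
D_RESIDUE_MONO = _formula_mass(_D_RESIDUE, _MONO)
WATER_MONO = _formula_mass(_WATER, _MONO)
A_RESIDUE_AVG = _formula_mass(_A_RESIDUE, _AVG)
D_RESIDUE_AVG = _formula_mass(_D_RESIDUE, _AVG)
WATER_AVG = _formula_mass(_WATER, _AVG)

_LABEL_RE = re.compile(r"^(?:A(\d+))?(?:D(\d+))?$")


@dataclass(frozen=True, order=True)
class Composition:
    """Counts of A (GlcNAc) and D (GlcN) units of one oligomer species."""

    nA: int
    nD: int

    def __post_init__(self) -> None:
        if self.nA < 0 or self.nD < 0:
            raise ValidationError(f"negative unit counts: nA={self.nA}, nD={self.nD}")
        if self.dp < 1:
            raise ValidationError("invalid composition: DP must be >= 1")

    @property
    def dp(self) -> int:
        return self.nA + self.nD

    @property
    def fa(self) -> float:
        return self.nA / self.dp

    @property
    def label(self) -> str:
        """Compact label in the field's convention: D4, A2, A1D3 ..."""
        parts = []
        if self.nA:
            parts.append(f"A{self.nA}")
        if self.nD:
            parts.append(f"D{self.nD}")
        return "".join(parts)

    @classmethod
    def from_label(cls, label: str) -> "Composition":
        m = _LABEL_RE.match(label.strip())
        if m is None or (m.group(1) is None and m.group(2) is None):
            raise ValidationError(f"unparsable composition label: {label!r}")
        return cls(int(m.group(1) or 0), int(m.group(2) or 0))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode ESI adduct: name, charge and total mass shift (Da)."""

    name: str
    charge: int
    mass_shift: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ConfigurationError(f"adduct charge must be >= 1, got {self.charge}")


ADDUCTS: dict[str, AdductSpec] = {
    "+H": AdductSpec("+H", 1, PROTON_MASS),
    "+2H": AdductSpec("+2H", 2, 2 * PROTON_MASS),
    "+Na": AdductSpec("+Na", 1, SODIUM_CATION_MASS),
}

# Short oligomers ionize predominantly singly charged in an ion trap;
# doubly protonated ions appear for longer chains.
DEFAULT_ADDUCT_RULES: dict[tuple[int, int], tuple[str, ...]] = {
    (1, 4): ("+H",),
    (5, 10): ("+H", "+2H"),
}

DEFAULT_SCAN_RANGE = (50.0, 2000.0)  # m/z, positive-mode survey scans


def composition_mass(c: Composition, monoisotopic: bool = True) -> float:
    """Neutral mass of an oligomer in Da (residue masses + one water)."""
    if monoisotopic:
        return c.nA * A_RESIDUE_MONO + c.nD * D_RESIDUE_MONO + WATER_MONO
    return c.nA * A_RESIDUE_AVG + c.nD * D_RESIDUE_AVG + WATER_AVG


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z of ``[M + adduct]^charge+`` for a neutral mass in Da."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ConfigurationError(f"unknown adduct: {adduct!r}") from None
    if neutral_mass <= 0:
        raise ValidationError(f"neutral mass must be > 0, got {neutral_mass}")
    return (neutral_mass + adduct.mass_shift) / adduct.charge


def _adducts_for_dp(dp: int, rules: Mapping[tuple[int, int], Sequence[str]]) -> list[str]:
    names: list[str] = []
    for (lo, hi), adds in rules.items():
        if lo <= dp <= hi:
            names.extend(adds)
    return names


class CandidateTable:
    """Table of (composition, adduct) candidates with theoretical m/z values.

    Backed by a pandas DataFrame with columns
    ``label, nA, nD, adduct, charge, mz, observable``; ``observable`` flags
    rows whose m/z lies inside the configured scan range.  The same CSV
    layout is both written and read.
    """

    COLUMNS = ["label", "nA", "nD", "adduct", "charge", "mz", "observable"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"candidate table missing columns: {missing}")
        dup = df.duplicated(subset=["nA", "nD", "adduct"])
        if dup.any():
            raise ValidationError("duplicate (composition, adduct) rows in candidate table")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def compositions(self) -> list[Composition]:
        seen = self.df[["nA", "nD"]].drop_duplicates()
        return [Composition(int(a), int(d)) for a, d in seen.itertuples(index=False)]

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["mz"] = out["mz"].map(lambda x: f"{x:.6f}")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CandidateTable":
        df = pd.read_csv(path)
        if "observable" not in df.columns:
            df["observable"] = True
        df["observable"] = df["observable"].astype(bool)
        return cls(df)


def enumerate_candidates(
    dp_min: int,
    dp_max: int,
    adduct_rules: Mapping[tuple[int, int], Sequence[str]] | None = None,
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
    monoisotopic: bool = True,
) -> CandidateTable:
    """Enumerate every (nA, nD) composition with dp_min <= DP <= dp_max,
    crossed with the adducts its DP is assigned by ``adduct_rules``.

    Rows whose theoretical m/z falls outside ``scan_range`` are kept but
    flagged unobservable.
    """
    if not (1 <= dp_min <= dp_max):
        raise ConfigurationError(f"need 1 <= dp_min <= dp_max, got {dp_min}..{dp_max}")
    rules = DEFAULT_ADDUCT_RULES if adduct_rules is None else dict(adduct_rules)
    if not rules or all(not v for v in rules.values()):
        raise ConfigurationError("adduct rules are empty")
    rows = []
    lo_mz, hi_mz = scan_range
    for dp in range(dp_min, dp_max + 1):
        names = _adducts_for_dp(dp, rules)
        if not names:
            raise ConfigurationError(f"no adducts configured for DP {dp}")
        for nA in range(dp + 1):
            comp = Composition(nA, dp - nA)
            mass = composition_mass(comp, monoisotopic=monoisotopic)
            for name in names:
                spec = ADDUCTS.get(name)
                if spec is None:
                    raise ConfigurationError(f"unknown adduct in rules: {name!r}")
                mz = adduct_mz(mass, spec)
                rows.append(
                    {
                        "label": comp.label,
                        "nA": comp.nA,
                        "nD": comp.nD,
                        "adduct": spec.name,
                        "charge": spec.charge,
                        "mz": mz,
                        "observable": lo_mz <= mz <= hi_mz,
                    }
                )
    return CandidateTable(pd.DataFrame(rows, columns=CandidateTable.COLUMNS))


def all_compositions(dp_min: int, dp_max: int) -> Iterable[Composition]:
    """All (nA, nD) with dp_min <= nA + nD <= dp_max, in (dp, nA) order."""
    for dp in range(dp_min, dp_max + 1):
        for nA in range(dp + 1):
            yield Composition(nA, dp - nA)
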