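"""Ground-truth digestion simulator and instrument forward model.

This module generates everything the pipeline consumes, with known truth:

* chitosan chains of configurable length distribution and fraction of
  acetylation (A/D units i.i.d. Bernoulli, i.e. a random acetylation
  pattern);
* an endo-cleavage simulator with per-subsite A/D acceptance weights: at
  each discrete time step every glycosidic bond is cleaved independently
  with probability ``1 - exp(-k dt)`` where ``k`` is ``k_max`` times the
  product of the acceptance weights of the units occupying the enzyme's
  subsites (an ``overhang`` factor substitutes for subsites that reach past
  a fragment end).  Endo action emerges naturally: no position is special;
* an RI forward model: every species contributes a Gaussian elution peak
  positioned by the mass-RT calibration, with area proportional to its
  mass and independent of DP and FA (the RI detector responds to mass
  concentration only);
* an MS forward model: per oligomer composition a total intensity
  proportional to mass times a DP-dependent ionization efficiency (maximal
  at DP 3), spread over scans inside the composition's DP elution window
  and over its configured adducts, with optional multiplicative log-normal
  noise.

Species of one DP co-elute on the real column (high-ionic-strength SEC
solvent), so the RI model places every oligomer of a DP at the nominal RT
of its fully deacetylated member, matching the DP window construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .calibration import CalibrationModel, Segment
from .chemistry import (
    A_RESIDUE_AVG,
    A_RESIDUE_MONO,
    D_RESIDUE_AVG,
    D_RESIDUE_MONO,
    DEFAULT_ADDUCT_RULES,
    DEFAULT_SCAN_RANGE,
    WATER_AVG,
    WATER_MONO,
    ADDUCTS,
    Composition,
    adduct_mz,
    composition_mass,
    enumerate_candidates,
)
from .errors import ConfigurationError, NoPolymerError, ValidationError
from .ms import Scan, SpectrumSeries, write_mzml
from .ri import Chromatogram, DPWindowMap, windows_from_calibration

# ---------------------------------------------------------------------------
# chains


def generate_chains(
    n: int,
    dp_distribution: Mapping | None = None,
    fa: float = 0.22,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Generate ``n`` chains as uint8 arrays (1 = A/GlcNAc, 0 = D/GlcN),
    ordered non-reducing to reducing end.

    ``dp_distribution`` specs: ``{"kind": "lognormal", "mean_dp": m,
    "sigma_ln": s}`` (default, mean 300, sigma 0.25), ``{"kind": "fixed",
    "dp": d}`` or ``{"kind": "uniform", "lo": a, "hi": b}``.  A/D units are
    drawn i.i.d. Bernoulli(fa): a random acetylation pattern.
    """
    if n < 1:
        raise ConfigurationError(f"need n >= 1 chains, got {n}")
    if not 0.0 <= fa <= 1.0:
        raise ConfigurationError(f"fa must be in [0, 1], got {fa}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    spec = dict(dp_distribution or {"kind": "lognormal", "mean_dp": 300.0, "sigma_ln": 0.25})
    kind = spec.pop("kind", None)
    if kind == "lognormal":
        mean_dp = float(spec.pop("mean_dp"))
        sigma = float(spec.pop("sigma_ln"))
        if mean_dp < 1 or sigma < 0:
            raise ConfigurationError("lognormal needs mean_dp >= 1 and sigma_ln >= 0")
        mu = np.log(mean_dp) - sigma**2 / 2
        lengths = np.maximum(np.rint(rng.lognormal(mu, sigma, n)).astype(int), 1)
    elif kind == "fixed":
        dp = int(spec.pop("dp"))
        if dp < 1:
            raise ConfigurationError("fixed dp must be >= 1")
        lengths = np.full(n, dp, dtype=int)
    elif kind == "uniform":
        lo, hi = int(spec.pop("lo")), int(spec.pop("hi"))
        if not 1 <= lo <= hi:
            raise ConfigurationError("uniform needs 1 <= lo <= hi")
        lengths = rng.integers(lo, hi + 1, n)
    else:
        raise ConfigurationError(f"unknown dp distribution kind: {kind!r}")
    if spec:
        raise ConfigurationError(f"unused dp distribution keys: {sorted(spec)}")
    return [(rng.random(L) < fa).astype(np.uint8) for L in lengths]


def chain_from_str(s: str) -> np.ndarray:
    """'ADDA' -> array([1, 0, 0, 1]); non-reducing end first."""
    if not s or set(s) - {"A", "D"}:
        raise ValidationError(f"chain string must be non-empty over {{A, D}}: {s!r}")
    return (np.frombuffer(s.encode(), dtype=np.uint8) == ord("A")).astype(np.uint8)


def chain_to_str(chain: np.ndarray) -> str:
    return "".join("A" if u else "D" for u in chain)


# ---------------------------------------------------------------------------
# subsite model


@dataclass(frozen=True)
class SubsiteModel:
    """Per-subsite A/D acceptance weights of an endo-glycosidase.

    ``weights`` maps subsite index (negative = non-reducing side of the
    scissile bond, positive = reducing side; no zero) to ``(wA, wD)`` in
    [0, 1].  ``k_max`` is the per-bond cleavage rate (1/min) when every
    subsite holds a perfectly accepted unit; ``overhang`` is the factor
    applied for subsites that reach past the end of the fragment.
    """

    weights: Mapping[int, tuple[float, float]]
    k_max: float = 0.005
    overhang: float = 1.0

    def __post_init__(self) -> None:
        if self.k_max <= 0:
            raise ConfigurationError(f"k_max must be > 0, got {self.k_max}")
        if not self.weights:
            raise ConfigurationError("subsite model needs at least one subsite")
        for s, (wa, wd) in self.weights.items():
            if s == 0:
                raise ConfigurationError("subsite index 0 does not exist")
            if not (0 <= wa <= 1 and 0 <= wd <= 1):
                raise ConfigurationError(f"subsite {s}: weights must be in [0, 1]")
        if not 0 <= self.overhang:
            raise ConfigurationError("overhang factor must be >= 0")

    @property
    def subsites(self) -> tuple[int, ...]:
        return tuple(sorted(self.weights))


def csnmn_preset(k_max: float = 0.005) -> SubsiteModel:
    """Qualitative CsnMN-like chitosanase preset.

    D-units accepted everywhere; A-units rejected at subsites -2..-1 and
    +1..+2 and tolerated with low weight at -3/+3.  The weights encode the
    enzyme's qualitative subsite preference only; they are not measured
    binding energies.
    """
    w = {s: (0.0, 1.0) for s in (-2, -1, 1, 2)}
    w.update({s: (0.3, 1.0) for s in (-3, 3)})
    return SubsiteModel(weights=w, k_max=k_max)


def strict_d_preset(k_max: float = 0.005) -> SubsiteModel:
    """Fully D-specific variant: A-units rejected at every subsite -3..+3."""
    return SubsiteModel(weights={s: (0.0, 1.0) for s in (-3, -2, -1, 1, 2, 3)}, k_max=k_max)


# ---------------------------------------------------------------------------
# digestion state


@dataclass(eq=False)
class DigestState:
    """Snapshot of the digestion at one time.

    Internally all chains live in one flat unit array; ``cut`` marks the
    severed bonds (inter-chain separators count as permanently cut).
    Fragment compositions are derived lazily and cached.
    """

    time: float
    units: np.ndarray  # uint8, shared across states
    cut: np.ndarray    # bool, len(units) - 1, snapshot

    @cached_property
    def _frag_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(nA, nD) per fragment, vectorized over cut positions."""
        ends = np.concatenate([np.flatnonzero(self.cut) + 1, [len(self.units)]])
        starts = np.concatenate([[0], ends[:-1]])
        cs = np.concatenate([[0], np.cumsum(self.units, dtype=np.int64)])
        nA = cs[ends] - cs[starts]
        lengths = ends - starts
        return nA.astype(np.int64), (lengths - nA).astype(np.int64)

    @property
    def frag_nA(self) -> np.ndarray:
        return self._frag_arrays[0]

    @property
    def frag_nD(self) -> np.ndarray:
        return self._frag_arrays[1]

    @property
    def frag_dp(self) -> np.ndarray:
        return self.frag_nA + self.frag_nD

    @property
    def n_chains(self) -> int:
        return len(self.frag_nA)

    @property
    def total_a(self) -> int:
        return int(self.frag_nA.sum())

    @property
    def total_d(self) -> int:
        return int(self.frag_nD.sum())

    def fragments(self) -> list[np.ndarray]:
        """Fragment unit arrays (views into the shared unit array)."""
        return np.split(self.units, np.flatnonzero(self.cut) + 1)

    def frag_masses(self, monoisotopic: bool = True) -> np.ndarray:
        if monoisotopic:
            return self.frag_nA * A_RESIDUE_MONO + self.frag_nD * D_RESIDUE_MONO + WATER_MONO
        return self.frag_nA * A_RESIDUE_AVG + self.frag_nD * D_RESIDUE_AVG + WATER_AVG

    def _pool_mask(self, dp_min: int, cutoff: int) -> np.ndarray:
        dp = self.frag_dp
        return (dp >= dp_min) & (dp <= cutoff)

    def pool_species(
        self, dp_min: int = 2, cutoff: int = 10, monoisotopic: bool = True
    ) -> dict[Composition, float]:
        """Total mass (Da-equivalents, arbitrary scale) per pool composition."""
        mask = self._pool_mask(dp_min, cutoff)
        if not mask.any():
            return {}
        key = self.frag_nA[mask] * 100_000 + self.frag_nD[mask]
        uniq, counts = np.unique(key, return_counts=True)
        out = {}
        for k, c in zip(uniq, counts):
            comp = Composition(int(k // 100_000), int(k % 100_000))
            out[comp] = float(c) * composition_mass(comp, monoisotopic=monoisotopic)
        return out

    def pool_mass_fractions(
        self, dp_min: int = 2, cutoff: int = 10, monoisotopic: bool = True
    ) -> dict[Composition, float]:
        pool = self.pool_species(dp_min, cutoff, monoisotopic)
        total = sum(pool.values())
        return {c: m / total for c, m in pool.items()} if total > 0 else {}

    def small_oligomer_share(
        self, dp_min: int = 2, cutoff: int = 10, monoisotopic: bool = True
    ) -> float:
        """True small-oligomer proportion: mass of DP dp_min..cutoff products
        relative to (small oligomers + everything above the cutoff).

        This is the two-class proportion the RI split measures — small
        oligomers vs polymers and large oligomers.  Fragments below
        ``dp_min`` (monomers) belong to neither class.
        """
        masses = self.frag_masses(monoisotopic)
        small = masses[self._pool_mask(dp_min, cutoff)].sum()
        large = masses[self.frag_dp > cutoff].sum()
        return float(small / (small + large))

    def average_product_fa(self, dp_min: int = 2, cutoff: int = 10) -> float:
        """Unit-count (molar) average FA of the oligomer product pool."""
        mask = self._pool_mask(dp_min, cutoff)
        dp_sum = int(self.frag_dp[mask].sum())
        if dp_sum == 0:
            raise ValidationError("empty product pool has no average FA")
        return int(self.frag_nA[mask].sum()) / dp_sum


@dataclass(frozen=True)
class PolymerStats:
    """Weight-average Mw, number-average Mn and dispersity DM = Mw/Mn."""

    mw: float
    mn: float

    @property
    def dispersity(self) -> float:
        return self.mw / self.mn


def true_polymer_stats(
    state: DigestState, cutoff: int = 10, monoisotopic: bool = True
) -> PolymerStats:
    """Mw = sum(m^2)/sum(m), Mn = sum(m)/n over fragments with DP > cutoff."""
    masses = state.frag_masses(monoisotopic)[state.frag_dp > cutoff]
    if len(masses) == 0:
        raise NoPolymerError(f"no fragments above DP {cutoff}")
    msum = masses.sum()
    return PolymerStats(mw=float((masses**2).sum() / msum), mn=float(msum / len(masses)))


# ---------------------------------------------------------------------------
# kinetics


def _shift(a: np.ndarray, k: int, fill) -> np.ndarray:
    """out[i] = a[i + k], padded with ``fill``."""
    out = np.full_like(a, fill)
    if k == 0:
        return a.copy()
    if k > 0:
        out[:-k] = a[k:]
    else:
        out[-k:] = a[:k]
    return out


def simulate_digestion(
    chains: Sequence[np.ndarray],
    model: SubsiteModel,
    timepoints: Sequence[float],
    dt: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[DigestState]:
    """Discrete-time stochastic endo-cleavage of a chain population.

    Every step of length ``dt`` minutes, each intact bond is cleaved
    independently with probability ``1 - exp(-k dt)``; ``k`` is the subsite
    model's rate for that bond in its current fragment context (fragment
    ends shorter than the subsite span contribute the overhang factor).
    States are recorded at the requested timepoints.  Total A and D unit
    counts are conserved exactly; the bond context is re-evaluated every
    step so newly created chain ends immediately affect their neighbours.
    """
    tps = [float(t) for t in timepoints]
    if any(b <= a for a, b in zip(tps[:-1], tps[1:])) or any(t < 0 for t in tps):
        raise ValidationError("timepoints must be non-negative and strictly increasing")
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    rng = rng if rng is not None else np.random.default_rng(seed)

    units = np.concatenate(chains).astype(np.uint8)
    n = len(units)
    cut = np.zeros(max(n - 1, 0), dtype=bool)
    pos = 0
    for ch in chains[:-1]:  # inter-chain separators: permanently cut bonds
        pos += len(ch)
        cut[pos - 1] = True

    # per-unit acceptance weight for each subsite (units never change)
    w = {
        s: np.where(units == 1, wa, wd).astype(np.float64)
        for s, (wa, wd) in model.weights.items()
    }
    ov = float(model.overhang)
    neg = sorted((s for s in model.subsites if s < 0), reverse=True)  # -1, -2, ...
    pos_s = sorted(s for s in model.subsites if s > 0)  # 1, 2, ...

    def bond_rates() -> np.ndarray:
        # bond i joins units i and i+1; subsite -m holds unit i-(m-1),
        # subsite +m holds unit i+m.  Occupancy of |m| >= 2 requires the
        # m-1 bonds between the scissile bond and that unit to be intact.
        u = ~cut
        r = np.full(n - 1, model.k_max)
        occ = np.ones(n - 1, dtype=bool)
        for s in neg:
            m = -s
            if m == 1:
                r *= w[s][:-1]
                continue
            occ = occ & _shift(u, -(m - 1), False)
            r *= np.where(occ, _shift(w[s][:-1], -(m - 1), 1.0), ov)
        occ = np.ones(n - 1, dtype=bool)
        for s in pos_s:
            m = s
            if m == 1:
                r *= w[s][1:]
                continue
            occ = occ & _shift(u, m - 1, False)
            r *= np.where(occ, _shift(w[s][1:], m - 1, 1.0), ov)
        return r

    states: list[DigestState] = []
    t = 0.0
    for tp in tps:
        n_steps = int(round((tp - t) / dt))
        for _ in range(n_steps):
            if n > 1:
                p = -np.expm1(-bond_rates() * dt)
                new = ~cut & (rng.random(n - 1) < p)
                cut |= new
        t = tp
        states.append(DigestState(time=tp, units=units, cut=cut.copy()))
    return states


# ---------------------------------------------------------------------------
# instrument forward models


def synthetic_column_calibration() -> CalibrationModel:
    """Synthetic three-segment Mw-RT calibration of an idealized SEC column.

    Emulates a 14-min UHPSEC run: 1000-10 kDa elute at 3.0-6.5 min,
    10-1 kDa at 6.5-9.0 min and 1-0.1 kDa at 9.0-12.0 min, each segment a
    straight line in ln(M) vs RT.  Purely synthetic: the coefficients are
    chosen for plausible elution order/spacing, not measured ones.
    """
    ln10 = np.log(10.0)

    def seg(m_lo, m_hi, rt_lo, rt_hi):
        b = (np.log(m_lo) - np.log(m_hi)) / (rt_hi - rt_lo)
        a = np.log(m_hi) - b * rt_lo
        return Segment(m_lo, m_hi, rt_lo, rt_hi, float(a), float(b), 1.0, 0)

    return CalibrationModel(
        "Mw",
        [
            seg(1e4, 1e6, 3.0, 6.5),
            seg(1e3, 1e4, 6.5, 9.0),
            seg(1e2, 1e3, 9.0, 12.0),
        ],
    )


DEFAULT_IONIZATION_EFFICIENCY: dict[int, float] = {
    1: 0.25, 2: 0.6, 3: 1.0, 4: 0.85, 5: 0.65,
    6: 0.5, 7: 0.4, 8: 0.3, 9: 0.22, 10: 0.15,
}


def render_ri(
    state: DigestState,
    model: CalibrationModel,
    peak_sigma: float = 0.02,
    noise_sigma: float = 0.0,
    baseline: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    runtime_min: float = 14.0,
    rate_hz: float = 10.0,
    response: float = 2e-5,
    coelute_dp: tuple[int, int] = (2, 10),
    monoisotopic: bool = True,
) -> Chromatogram:
    """Render a digestion state as an RI chromatogram.

    Each species contributes a Gaussian of area ``response * total mass``
    (RI response independent of DP and FA) centred at the calibrated RT of
    its mass; oligomers with DP inside ``coelute_dp`` are placed at the
    nominal RT of the fully deacetylated member of their DP (co-elution).
    Additive Gaussian noise and a constant baseline follow.
    """
    if peak_sigma <= 0:
        raise ConfigurationError("peak_sigma must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    t = np.arange(0.0, runtime_min + 0.5 / (rate_hz * 60), 1.0 / (rate_hz * 60))
    sig = np.zeros_like(t)

    key = state.frag_nA * 100_000 + state.frag_nD
    uniq, counts = np.unique(key, return_counts=True)
    lo_dp, hi_dp = coelute_dp
    nominal_rt = {
        d: model.predict_rt(composition_mass(Composition(0, d), monoisotopic))[0]
        for d in range(lo_dp, hi_dp + 1)
    }
    norm = 1.0 / (peak_sigma * np.sqrt(2 * np.pi))
    for k, c in zip(uniq, counts):
        nA, nD = int(k // 100_000), int(k % 100_000)
        comp = Composition(nA, nD)
        mass = composition_mass(comp, monoisotopic)
        rt = nominal_rt[comp.dp] if lo_dp <= comp.dp <= hi_dp else model.predict_rt(mass)[0]
        if rt + 5 * peak_sigma < t[0] or rt - 5 * peak_sigma > t[-1]:
            continue
        i0 = np.searchsorted(t, rt - 5 * peak_sigma)
        i1 = np.searchsorted(t, rt + 5 * peak_sigma)
        amp = response * mass * c * norm
        sig[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - rt) / peak_sigma) ** 2)
    if noise_sigma > 0:
        sig = sig + rng.normal(0.0, noise_sigma, size=len(sig))
    sig = sig + baseline
    return Chromatogram(t, sig, {"time_min": state.time, "synthetic": True})


def render_ms(
    state: DigestState,
    windows: DPWindowMap,
    efficiency: Mapping[int, float] | None = None,
    scans_per_window: int = 5,
    lognorm_sigma: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    adduct_rules: Mapping | None = None,
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
    monoisotopic: bool = True,
    response: float = 1.0,
) -> SpectrumSeries:
    """Render the oligomer pool of a state as a centroided MS run.

    Each composition's total intensity is ``response * mass * e(DP)``
    (times log-normal noise when ``lognorm_sigma > 0``), split evenly over
    its adducts and over ``scans_per_window`` scans placed inside its DP
    elution window.  Centroids outside the scan range are unobservable and
    dropped, exactly as on the instrument.
    """
    eff = dict(DEFAULT_IONIZATION_EFFICIENCY if efficiency is None else efficiency)
    rules = DEFAULT_ADDUCT_RULES if adduct_rules is None else dict(adduct_rules)
    rng = rng if rng is not None else np.random.default_rng(seed)
    dps = windows.dps
    for d in dps:
        if d not in eff:
            raise ConfigurationError(f"no ionization efficiency for DP {d}")
    pool = state.pool_species(dp_min=min(dps), cutoff=max(dps), monoisotopic=monoisotopic)

    per_scan: dict[int, tuple[list[float], list[float]]] = {}
    scan_times: list[tuple[float, int]] = []
    for d in dps:
        lo, hi = windows.window_for(d)
        for j in range(scans_per_window):
            scan_times.append((lo + (j + 0.5) * (hi - lo) / scans_per_window, d))
    scan_times.sort()

    centroids: dict[int, tuple[list[float], list[float]]] = {
        i: ([], []) for i in range(len(scan_times))
    }
    for comp, mass in pool.items():
        total = response * mass * eff[comp.dp]
        if lognorm_sigma > 0:
            total *= rng.lognormal(0.0, lognorm_sigma)
        adduct_names = [nm for (lo, hi), names in rules.items()
                        if lo <= comp.dp <= hi for nm in names]
        if not adduct_names:
            raise ConfigurationError(f"no adducts configured for DP {comp.dp}")
        scan_ids = [i for i, (rt, d) in enumerate(scan_times) if d == comp.dp]
        share = total / (len(adduct_names) * len(scan_ids))
        neutral = composition_mass(comp, monoisotopic)
        for nm in adduct_names:
            mz = adduct_mz(neutral, ADDUCTS[nm])
            if not scan_range[0] <= mz <= scan_range[1]:
                continue
            for i in scan_ids:
                centroids[i][0].append(mz)
                centroids[i][1].append(share)

    scans = []
    for i, (rt, _) in enumerate(scan_times):
        mzs, ints = centroids[i]
        order = np.argsort(mzs)
        scans.append(Scan(rt, np.array(mzs)[order], np.array(ints)[order]))
    return SpectrumSeries(scans=scans, scan_range=scan_range)


# ---------------------------------------------------------------------------
# scenario: a complete simulated live digestion written to disk


@dataclass
class DigestionScenario:
    """A complete simulated live-digestion experiment.

    Defaults emulate the reference experiment at desk scale: an FA 0.22
    chitosan substrate (log-normal chain lengths, mean DP 300), a
    CsnMN-like D-preferring chitosanase, 21 samples over 300 min (one
    every 15 min), 3 ug injected per sample, DP 10 oligomer cutoff.
    """

    n_chains: int = 500
    dp_distribution: dict = field(
        default_factory=lambda: {"kind": "lognormal", "mean_dp": 300.0, "sigma_ln": 0.25}
    )
    fa: float = 0.22
    subsite_model: SubsiteModel = field(default_factory=csnmn_preset)
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 301, 15))
    dt: float = 0.1
    injected_ug: float = 3.0
    cutoff_dp: int = 10
    dp_min: int = 2
    peak_sigma: float = 0.02
    ri_noise_rel: float = 0.0  # additive RI noise sigma as fraction of trace max
    ms_lognorm_sigma: float = 0.0
    scans_per_window: int = 5
    seed: int = 42

    def simulate(self) -> list[DigestState]:
        ss = np.random.SeedSequence(self.seed)
        rng_chains, rng_digest = (np.random.default_rng(s) for s in ss.spawn(2))
        chains = generate_chains(self.n_chains, self.dp_distribution, self.fa, rng=rng_chains)
        return simulate_digestion(chains, self.subsite_model, self.timepoints,
                                  dt=self.dt, rng=rng_digest)


def write_scenario(
    scenario: DigestionScenario, out_dir: str | Path,
    states: list[DigestState] | None = None,
) -> Path:
    """Simulate a scenario and write every pipeline input to ``out_dir``.

    Writes the calibration JSON, DP window map CSV, candidate table CSV,
    one RI CSV and one mzML file per timepoint, a ground-truth CSV and a
    run manifest YAML.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = synthetic_column_calibration()
    windows = windows_from_calibration(model, scenario.dp_min, scenario.cutoff_dp)
    candidates = enumerate_candidates(scenario.dp_min, scenario.cutoff_dp)

    model.to_json(out / "calibration.json")
    windows.to_csv(out / "windows.csv")
    candidates.to_csv(out / "candidates.csv")

    if states is None:
        states = scenario.simulate()
    ss = np.random.SeedSequence(scenario.seed + 1)
    rngs = [np.random.default_rng(s) for s in ss.spawn(2 * len(states))]

    entries = []
    truth_rows = []
    for i, st in enumerate(states):
        clean = render_ri(st, model, peak_sigma=scenario.peak_sigma,
                          coelute_dp=(scenario.dp_min, scenario.cutoff_dp))
        if scenario.ri_noise_rel > 0:
            sigma = scenario.ri_noise_rel * float(clean.signal.max())
            noisy = Chromatogram(
                clean.time, clean.signal + rngs[2 * i].normal(0, sigma, len(clean)),
                clean.metadata,
            )
        else:
            noisy = clean
        ri_path = out / f"ri_t{int(round(st.time)):03d}.csv"
        _write_ri_csv(noisy, ri_path)
        series = render_ms(st, windows, scans_per_window=scenario.scans_per_window,
                           lognorm_sigma=scenario.ms_lognorm_sigma, rng=rngs[2 * i + 1])
        ms_path = out / f"ms_t{int(round(st.time)):03d}.mzML"
        write_mzml(series, ms_path)
        entries.append({"time_min": st.time, "ri_csv": ri_path.name, "mzml": ms_path.name})

        fractions = st.pool_mass_fractions(scenario.dp_min, scenario.cutoff_dp)
        share = st.small_oligomer_share(scenario.dp_min, scenario.cutoff_dp)
        try:
            stats = true_polymer_stats(st, scenario.cutoff_dp)
            mw, mn = stats.mw, stats.mn
        except NoPolymerError:
            mw = mn = float("nan")
        fa = (st.average_product_fa(scenario.dp_min, scenario.cutoff_dp)
              if fractions else float("nan"))
        for comp, frac in sorted(fractions.items()):
            truth_rows.append(
                f"{st.time:g},{comp.label},{comp.nA},{comp.nD},{frac:.9g},"
                f"{share:.9g},{mw:.9g},{mn:.9g},{fa:.9g}"
            )
        if not fractions:
            truth_rows.append(f"{st.time:g},,,,,{share:.9g},{mw:.9g},{mn:.9g},nan")

    header = "timepoint_min,label,nA,nD,true_mass_fraction,true_small_share,true_mw,true_mn,true_avg_fa"
    (out / "truth.csv").write_text(header + "\n" + "\n".join(truth_rows) + "\n")

    manifest = {
        "runs": entries,
        "calibration": "calibration.json",
        "windows": "windows.csv",
        "candidates": "candidates.csv",
        "injected_ug": scenario.injected_ug,
        "cutoff_dp": scenario.cutoff_dp,
        "mz_tol": 0.3,
        "rt_offset": 0.0,
        "fa_mode": "molar",
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def _write_ri_csv(c: Chromatogram, path: Path) -> None:
    lines = ["time_min,riu"]
    lines.extend(f"{t:.8g},{s:.8g}" for t, s in zip(c.time, c.signal))
    path.write_text("\n".join(lines) + "\n")
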