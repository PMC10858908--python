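# Methods

This note documents the models behind `chitosec`, the defaults and why
they were chosen, what the synthetic data generator does and does not
emulate, and the package's known limitations.  Every number quoted here
is computed by the test suite or by `scripts/acceptance.py`.

## Analysis chain

### Mass–retention-time calibration

In size-exclusion chromatography larger analytes elute earlier, and over
a limited mass range ln *M* is close to linear in retention time.  A
single line does not span three decades of mass, so the calibration is
segmented — by default 0.1–1, 1–10 and 10–1000 kDa, each fitted by OLS of
ln *M* on RT.  Conventions, chosen for determinism:

* A standard whose mass falls exactly on a segment bound belongs to the
  lower-mass segment; likewise, prediction at a shared boundary uses the
  lower-mass / later-RT segment.
* Prediction outside every fitted range uses the nearest segment and
  raises an `extrapolated` flag — never silently.  In particular masses
  above the fitted range are always flagged.
* The sample RT is the RT of the RI signal peak maximum of the lightly
  smoothed trace (default 7 samples at 10 Hz ≈ 0.7 s), taking the
  *earliest* sample on ties.  No sub-sample interpolation: one grid step
  at 10 Hz corresponds to ~0.15–0.22% in mass given the fitted slopes,
  well under fit uncertainty.

M_n mode is structurally identical to M_w mode; the model records which
statistic it maps so the two are never mixed.

### RI processing

The RI detector responds to mass concentration essentially independently
of chitosan DP and F_A, so baseline-corrected areas are relative masses.

* **Baseline**: rolling mean (default 0.1 min) → rolling minimum
  (default 12 min) → rolling mean.  Two deliberate choices: smoothing
  *before* the minimum, because the minimum of raw noise sits several σ
  below the true baseline and would bias every area high; and a window
  almost as long as the run, because mid-digestion the polymer band is a
  several-minute hump that a short rolling minimum would carve into,
  biasing the polymer area low by up to ~9 percentage points of the
  small-oligomer share.
* **Per-DP quantification** uses fixed RT windows, not per-peak matching:
  species of one DP co-elute, and windows stay robust when neighbouring
  peaks shoulder.  Windows are half-open [rt_lo, rt_hi), derived either
  from the calibration (each DP centred at the predicted RT of its fully
  deacetylated member, bounds midway between neighbours) or from a
  reference oligomer-ladder run.
* The polymer/large-oligomer region runs from the void time (default
  2 min) to the start of the DP-10 window; DP > 10 material is lumped
  there.  The small-oligomer share is area(DP 2–10) / (area(DP 2–10) +
  polymer area) — a two-class proportion; monomers (no DP-1 window by
  default) belong to neither class and are invisible to it.

### MS harvest

One arbitrary intensity per candidate composition per injection: sum the
centroids within ±0.3 Da (unit-resolution ion trap default) of each
adduct m/z, over scans whose RT (plus a constant RI-vs-MS path offset,
default 0) falls in the composition's DP window, then sum over adducts.
Sums, not maxima, because they are invariant to how the signal is
apportioned across scans.  A centroid inside several candidates'
tolerance windows goes to the nearest theoretical m/z; exact ties are
split equally.  Default adduct rules: DP 1–4 → {+H}, DP 5–10 →
{+H, +2H}; monoisotopic masses throughout (one consistent convention;
relative quantities are insensitive to the mono/average choice).
Candidates outside the m/z 50–2000 scan range are kept but flagged
unobservable.

### RI/MS fusion

Weight fraction of species *s* of DP *d* in the DP ≤ 10 pool =
(RI area share of *d*) × (MS intensity share of *s* within *d*).
Within-DP MS ratios are read as *mass* ratios, because the response
factors that justify the fusion were established with equal injected
masses.  A DP with RI area but zero total MS intensity is reported as an
explicit `DP{d}_unassigned` record carrying the whole DP share — an
RI/MS inconsistency signal, never dropped.  Amounts are fraction × pool
share × injected mass (default 3 µg).  The pool-average F_A is
mole-based (fraction of A among all monomer units); a weight-based
variant is available behind `fa_mode="weight"` — the difference is
second-order for mixed pools.

## Synthetic data generator

The generator produces the reference conditions all end-to-end tests run
on: 500 chains, log-normal DP distribution with mean 300 and σ_ln = 0.25,
F_A 0.22 with A/D units i.i.d. Bernoulli (random P_A), 21 timepoints over
300 min, 3 µg per injection.  σ_ln = 0.25 (Đ_M ≈ 1.06) keeps the
peak-maximum mass within ~3% of the true M_w (the two differ by the
factor exp(σ_ln²/2) for a log-normal mass distribution), so the
peak-maximum convention can be validated directly against the generator.

**Kinetics.**  Discrete-time per-bond Bernoulli cleavage: every step of
dt = 0.1 min, each intact bond is cut with probability 1 − exp(−k·dt),
where k = k_max × Π (subsite acceptance weight of the occupying unit)
over subsites −3…+3, with a factor `overhang` (default 1) for subsites
reaching past a fragment end.  Endo action emerges because no position is
special.  This is simpler than event-driven simulation and adequate at
small dt; at dt = 0.1 min and the default rates, per-step cleavage
probabilities stay below ~5·10⁻⁴, so the discretization error is
negligible against run-to-run variation.  The D-preferring chitosanase
preset sets w(D) = 1 everywhere, w(A) = 0 at subsites ±1, ±2 and
w(A) = 0.3 at ±3; a fully D-specific variant sets w(A) = 0 everywhere.
Both are qualitative presets, not measured binding energies.
k_max = 0.005 min⁻¹ places the digestion's half-conversion of cleavable
material near the middle of the 300-min window — a realistic bench time
course.  All stochastic operations take explicit seeds; reproducibility
is a contract.

**Instrument forward model.**  Each species contributes a Gaussian RI
peak (σ = 0.02 min, a realistic UHPLC oligomer peak width) of area ∝
mass, positioned by the synthetic column calibration; oligomers of one DP
are placed at their DP's nominal RT (co-elution, matching the window
construction).  MS: total intensity ∝ mass × e(DP) with e maximal at
DP 3, split over adducts and over 5 scans inside the DP window, written
as standard centroided mzML.  Noise: additive Gaussian on the RI trace
(specified as a fraction of the trace maximum), multiplicative log-normal
on each composition's MS intensity.

**What the generator does *not* emulate** — and hence what passing tests
do not show about real data: real (heterogeneously deacetylated)
chitosans have *blocky* acetylation patterns, not Bernoulli ones, which
markedly changes which A-containing oligomers appear early; real peaks
tail; ionization efficiency within a DP is similar but not identical
(the very reason the method is "semi-quantitative"); detector drift,
carry-over, in-source fragmentation, isotope envelopes and transglycosylation
are absent; and with the overhang factor at 1, fragment ends cleave at
least as fast as interiors, producing monomers (~15% of mass by 300 min)
that a real chitosanase, needing several filled subsites, would not
release.

## Numerical conventions and degenerate inputs

Zero-mass or DP-0 compositions, non-monotone time axes, overlapping DP
windows, all-zero area vectors, empty product pools and empty polymer
pools all raise typed errors rather than propagating NaNs; the pipeline
reports NaN only for quantities that are genuinely undefined at a
timepoint (average F_A of an empty pool, peak M_w of an empty polymer
region) and logs it.  Exported CSVs format floats to 6 significant
digits, making re-runs on identical inputs byte-identical.

## Known limitations

* Weight fractions are relative to the DP 2–10 pool; there is no
  internal standard, so absolute µg values inherit the accuracy of the
  injected-mass figure and of the RI split.
* P_A within one (DP, F_A) is not resolved — a property of the method
  itself, not of this implementation.
* The peak-maximum M_w convention underestimates the true M_w of broad
  distributions (factor exp(σ_ln²/2) for log-normal); for dispersities
  ≥ 1.5 the M_w distribution view should be preferred.
* Late in digestion, when the polymer pool is nearly exhausted, the
  peak maximum can hop between the discrete DP 11–20 oligomer peaks,
  so the reported peak-max M_w is no longer monotone even though the
  underlying degradation is.
* With realistic MS noise (log-normal σ = 0.05), single-species weight
  fractions carry an effective ~5–7% relative uncertainty; across the
  ~160 (species, timepoint) observations of a full time course the worst
  single deviation is expected near 3σ (~20%), even though ~95% of
  species lie within 10%.
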