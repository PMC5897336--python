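# Methods

## The model

A prototypical two-component system (TCS) couples a sensor histidine
kinase (SK) to a response regulator (RR). The SK autophosphorylates on a
conserved histidine at a rate that rises with the input ligand, transfers
the phosphoryl group to the RR, and — being bifunctional — also
dephosphorylates phosphorylated RR (RR~P). Transcriptional output is a
Hill function of [RR~P]; the detection threshold K_1/2 is the input
concentration at which output is half-maximal.

`tcstune.tcs_model` implements the two-ODE mass-action reduction

```
d[SK~P]/dt = κ·k_auto(I)·(SK_tot − SK~P) − k_t·SK~P·(RR_tot − RR~P)
d[RR~P]/dt = k_t·SK~P·(RR_tot − RR~P) − φ·k_phos(I)·(SK_tot − SK~P)·RR~P − k_bg·RR~P
```

with k_auto(I) increasing and k_phos(I) decreasing along a Hill in the
input I (half-point `k_input_half`, coefficient `h_input`). Input coupling
is configurable — `dual` (default, both arms respond to input), `kinase`
(phosphatase input-blind) or `phosphatase` (constitutively active kinase)
— because bifunctional SKs of the NarX type modulate both reactions.
κ (`kappa`) and φ (`phi`) are dimensionless scale factors on kinase and
phosphatase activity; κ = φ = 1 reproduces the unscaled model exactly, so
a 1%–10,000% phosphatase sweep is `phi ∈ [0.01, 100]`.

**Assumptions.** Mass-action kinetics with conserved SK and RR totals; no
explicit SK·RR complexes, no transcription/translation dynamics of the
reporter (output is a transcription *rate*, not accumulated protein), no
stochasticity, no cross-talk to other RRs. A small SK-independent RR~P
decay `k_dephos_bg` represents background hydrolysis and keeps the
steady state unique and well-conditioned.

**Steady-state solver.** On the SK~P nullcline, SK~P is an explicit
function of RR~P, which reduces the system to a scalar balance in RR~P on
[0, RR_tot]. The balance is positive at 0 and negative at RR_tot whenever
any dephosphorylation path exists, so Brent's method brackets the root; a
guarded Newton polish pushes both residuals to ~1e-14 (the accepted
tolerance is 1e-9 in absolute rate units). Degenerate regimes (no kinase
flux, no transfer, no dephosphorylation) are resolved in closed form.
Long-time ODE integration (LSODA to t = 1e6 s, rtol 1e-10) from the
unphosphorylated state serves as an independent oracle; the two agree to
better than 1e-12 relative across random parameter sets spanning two
decades around the defaults.

**Default parameters** (documented desk-scale set, chosen once so that
RR~P traverses the promoter's RR~P_1/2 within the simulated input range):
SK_tot = 1 µM, RR_tot = 10 µM, k_auto = 0.01→1 s⁻¹, k_input_half = 10 µM,
h_input = 1, k_t = 1 µM⁻¹s⁻¹, k_phos = 0.5→0.05 µM⁻¹s⁻¹,
k_bg = 10⁻³ s⁻¹; promoter v_min = 1, v_max = 1000 (output units),
RR~P_1/2 = 1 µM, Hill 1.5. With these values the wild-type basal RR~P
(≈ κ·k_auto(0)/(φ·k_phos(0)) = 0.02 µM) sits well below RR~P_1/2 and the
saturating value (RR-limited at 10 µM) well above it, which is what makes
the threshold tunable without immediate dynamic-range collapse.

**Threshold extraction.** K_1/2 of a simulated curve is located by
log-linear interpolation between the two grid points bracketing
(min+max)/2. The zero-input point is prepended outside the log grid and
never interpolated across; if numerical jitter (< 1e-12) produces several
bracketing intervals, the lowest-input bracket is used. Sweeps use a grid
of 65 log-spaced points spanning ±4 decades around `k_input_half` so that
thresholds shifted ~2,000-fold by extreme activity scales stay bracketed.

**iso-SK mixtures.** Two SK pools (wild type, and a mutant with
phosphatase scale φ_mut) share one RR pool at fixed total SK. Each pool's
SK~P is eliminated on its own nullcline, leaving the same scalar RR~P
balance; a fraction-1 (or 0) mixture is numerically identical to the pure
simulation because the empty pool contributes exact zeros.

## Hill inference

Dose-response data are pooled across replicates/days and fit to
y = low + (high − low)·xⁿ/(K_1/2ⁿ + xⁿ) by weighted least squares
(lmfit/leastsq), each residual divided by the mean observed response at
its dose so both plateaus are fit on comparable relative scales. Zero
doses enter at x = 0 exactly. Initial guesses: low/high from the min/max
dose means, K_1/2 at the geometric mean of positive doses, n = 1
(bounds: low, high ≥ 0; K_1/2 > 0; n ∈ [0.1, 10]). Weight denominators
are floored (default 1 MEFL; pass the LOD when known) against
non-positive means after autofluorescence subtraction. The reported RSS
is verified in tests against an independent recomputation of the
objective.

**Confidence intervals** are profile F-test bounds: the parameter is
fixed on an adaptive grid (multiplicative steps for K_1/2 and n, additive
for low/high; ≤ 50 refits per side), the others refit with the same
weights, and the bound interpolated where
F = (RSS_fixed − RSS_min)/(RSS_min/(n_obs − 4)) crosses the
F(1, n_obs − 4) quantile. A side that never crosses is reported at the
search-range end and flagged unbounded; non-crossing lower bounds for
non-negative parameters are reported as 0 (intervals like "0–23 µM").
RSS_min is floored at 1e-30 so exact fits yield zero-width intervals. On
the synthetic study conditions (CV 10%, 12 doses + zero, 3 replicates)
the 95% interval covers the true K_1/2 in ≈ 94–98% of seeded runs.

**Derived quantities.** `hill_invert` solves the Hill equation for x
(x = K_1/2·(r/(1−r))^(1/n), r the fractional activation) and is the basis
of both the iso-SK induction design (split a total SK expression target
between two inducible pools and invert each inducer curve) and soil
reporting (invert a nitrate standard curve at a measured fluorescence;
readings outside the open (low, high) window return below-detection /
saturated statuses rather than extrapolated numbers). Fold change
substitutes the LOD (3σ of autofluorescence) for sub-LOD values and flags
the result as a lower bound. Dynamic range is high/low; amplitude range
high − low.

## Cytometry quantification chain

Fixed order, enforced by the single entry point `process_sample`:

1. **Trim** the first 250 and last 100 time-ordered events.
2. **Density gate**: 2-D histogram (64×64 bins) on log10(FSC), log10(SSC)
   over each channel's observed range; events ranked by their bin count
   (ties by acquisition order) and the top ⌈fraction·N⌉ kept
   (default 10%). A fixed binned estimator was chosen over KDE for
   determinism and testability.
3. Optional **FL3 floor** (constitutive-marker selection for the soil
   workflow).
4. **Bead calibration**: least-squares line of log10(MEFL) on
   log10(FL1 peak) over ≥ 3 bead peaks; applied to event FL1.
5. **Geometric mean**, then autofluorescence subtraction; sfGFP below the
   LOD is flagged. Channel values are floored at 1 detector unit before
   log transforms and the floored count reported.

## Synthetic data

Generators are pure functions of (ground truth, seed): noise is unit-mean
multiplicative log-normal (fluorescence populations are roughly
log-normal and summarized by geometric mean) with a per-replicate
day-effect multiplier whose sd defaults to half the noise CV — hence
exactly zero for noiseless configs. Study-condition defaults: dose
responses from (low = 100, high = 10,000 MEFL, K_1/2 = 50 µM, n = 1.5)
at 12 log-spaced doses + zero, 3 replicates, CV 10%; cytometry samples of
20,350 events (so trim then 10% gate leaves 2,000) with a tight cell
cluster (log10 scatter sd 0.04), 10% diffuse debris, FL1 median 500 MEFL
(ln-sd 0.4) pushed back through a bead line the bead peaks sit on
exactly; inducer curves with zero basal so fractional splits of a total
target are exact; soil standard (low = 50, high = 40,000 MEFL,
K_1/2 = 100 µM, n = 1.5) with CV 15% samples.

The soil "responsive window" is defined a priori as 10–70% activation of
the standard: first-order error propagation through the inverse Hill
gives d(ln x) = d(ln y)/(n·(1 − r)), so at r = 0.7 and CV 15% a report is
within twofold at ≈ 2σ, while above r ≈ 0.8 the inversion amplifies noise
past the twofold criterion — the saturating region is not a quantitative
readout and is excluded by design, mirroring how standard curves are used
in practice.

**What the generators do not emulate:** instrument saturation and
digitization, spectral spillover between channels, correlated
scatter/fluorescence within cells, autofluorescence heterogeneity, dose
pipetting error, and real day-to-day variance structure. Passing tests
therefore demonstrate the correctness and calibration of the computation,
not the biology of any particular strain.

## Motif tabulation

The G2-box scan is the literal pattern G.G.G over 5-residue windows
(overlaps allowed), which enforces the G1/G3/G5 presence rule; the hot
spot is the window's second residue, reported in 1-based protein
coordinates (hot spot = start + 1). Upstream domain-architecture
filtering, clustering and HMM alignment are out of scope; a per-protein
`search_start` stands in for the "C-terminal to the HisKA domain"
constraint. Tabulation counts one hit per sequence by default (SKs carry
a single CA domain); `per_sequence="all"` counts every window. Hydropathy
annotation uses the Kyte–Doolittle scale (the field default).

## Problem sizes and numerical choices

Monte-Carlo sizes used by the test suite and acceptance script — 100
random parameter sets for the ODE oracle, 200 seeded datasets for
coverage, 500 for bias, 25 soil experiments (600 reports), 1,000 random
sequences for the scanner oracle, 10,000 proteins for tally convergence —
are the package's documented study conditions; each completes in seconds
on a single core. Tolerances: steady-state residuals < 1e-9; oracle
agreement 1e-6 relative with an absolute floor of 1e-9·RR_tot for
near-zero species; inversion round-trip 1e-10; noiseless fit recovery
1e-6.

## Known limitations

- The ODE reduction omits explicit SK·RR complexes; systems where complex
  sequestration dominates may shift quantitatively (the monotone
  threshold law is robust in our explorations, but not proven for that
  formulation).
- Profile CIs assume approximately Gaussian weighted residuals;
  heavy-tailed noise or strong day effects will degrade calibration.
- The density gate's fixed 64×64 binning can fragment very small samples
  (< a few hundred events); the gate refuses < 50 events outright.
- `fold_change` expects autofluorescence-subtracted inputs; it does not
  re-subtract.
- The motif scanner has no notion of domain context beyond
  `search_start`; it will happily report G.G.G matches in non-kinase
  proteins.
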