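# Methods

`magflux` simulates and quantifies time-lapse ion-imaging assays of
Na⁺-coupled Mg²⁺ extrusion in cultured cells — the kind of experiment used to
establish that the CNNM4 transporter is an electroneutral 2 Na⁺ : 1 Mg²⁺
exchanger.  This note documents the model, the measurement chain, the
defaults and the choices made where the design was genuinely open.

## Whole-cell model

Each cell carries two state variables, free intracellular Mg²⁺ and Na⁺
(mM).  The exchanger extrudes Mg²⁺ with Hill-type activation by
extracellular Na⁺ and Michaelis saturation in intracellular Mg²⁺:

    J_ex = a · Vmax · [Na⁺]ₒⁿ / (K_Aⁿ + [Na⁺]ₒⁿ) · [Mg²⁺]ᵢ / (Km + [Mg²⁺]ᵢ)

with `J_ex` in mM·min⁻¹ (positive = Mg²⁺ efflux) and `a` the condition
activity scale (wild type 1, mock 0, Jalili-syndrome mutants S200Y/L324P
0.05 by default — residual mutant activity is a parameter because the
bench observation is "very weak, if any" rather than strictly zero).
Each transport cycle moves `stoich` Na⁺ inward per Mg²⁺ extruded
(default 2), so d[Na⁺]ᵢ/dt carries a `stoich · J_ex` term.  The
exchanger reverses — Mg²⁺ influx, Na⁺ efflux — when the Na⁺ gradient is
outward ([Na⁺]ₒ < [Na⁺]ᵢ) and the Mg²⁺ gradient is inward, using the
same Vmax/Km scaffold driven by intracellular Na⁺ and extracellular
Mg²⁺.  This is the smallest rule that reproduces reverse-mode Mg²⁺
loading in Na⁺-free, 10 mM Mg²⁺ buffer.

Around the exchanger sit three background fluxes:

* an inward-only Mg²⁺ channel leak `p_mg · residual(CoHex) · max([Mg²⁺]ₒ − [Mg²⁺]ᵢ, 0)`,
  inhibited by cobalt(III) hexammine with tabulated residual activity
  {1 mM: 0.4, 3 mM: 0.15};
* a background Na⁺ influx `p_na · max([Na⁺]ₒ − [Na⁺]ᵢ, 0)`;
* a first-order Na⁺ pump `k_pump · ([Na⁺]ᵢ − baseline)` relaxing toward
  a 10 mM resting level.

Mg²⁺ buffering is ignored: free Mg²⁺ is the state variable, and
cytosolic buffering would only rescale `Vmax` at this level of
description.  There are no membrane-potential dynamics; the predicted
membrane current is pure charge bookkeeping, `(stoich − 2)` elementary
charges per cycle scaled by cell volume (2 pL) and capacitance (20 pF),
identically zero for the electroneutral 2:1 exchanger.

Integration is fixed-step RK4 with dt = 1 s, steps never straddling
buffer-segment boundaries.  The dynamics are non-stiff at these rates;
a fixed step makes trajectories bit-reproducible, which adaptive
stepping would not.  A step that drives a concentration negative beyond
1 nM aborts with a numeric error; sub-nanomolar undershoot is clipped
to zero.

## Protocols

Protocols are contiguous timed buffer segments.  The canonical recipes:
loading buffer with 78.1 mM Na⁺ and 40 mM Mg²⁺; Mg²⁺-free buffer in
which the MgCl₂ is replaced by 60 mM NaCl (138.1 mM Na⁺ total);
Na⁺-free variants substitute NMDG-Cl, which carries no flux.  Shipped
presets:

* `extrusion` — 40 s baseline in loading buffer, then Mg²⁺ depletion
  (120 s).  The depletion onset is the analysis time origin.
* `titration` — the extrusion protocol with the depletion buffer at a
  chosen Na⁺ level (default series 0, 9.8, 19.5, 39, 78.1, 138.1 mM,
  fractions of the two buffer Na⁺ concentrations; NMDG balances).
* `phases_1_4` — depletion with Na⁺ (phase 1), 40 mM Mg²⁺ re-addition
  (phase 2), Mg²⁺- and Na⁺-free (phase 3), Na⁺ restoration (phase 4);
  160 s phases so segment boundaries sit on the 20 s sampling grid.
* `loading` — reverse-mode assay: unloaded cells, 10 mM Mg²⁺ /
  0 mM Na⁺ loading step, then Mg²⁺-free Na⁺-replete efflux.

Calibration episodes are appended after the experimental segments: a
zero-ion plateau and a saturating plateau (A23187 + EDTA and A23187 +
50 mM Mg²⁺ for Mg²⁺ probes; gramicidin in Na⁺-free and Na⁺-replete
buffer for SBFI), each 120 s (≥ 5 samples).  During these the simulator
clamps the *observed* ion at zero or saturation; the underlying state
variables keep evolving but are not read.

## Observation model

Sampling every 20 s.  For the ratiometric probes (Mag-fura2 for Mg²⁺,
Kd = 1.5 mM; SBFI for Na⁺, Kd = 11.3 mM) the noiseless excitation ratio
R = F₁/F₂ follows

    R(c) = (Rmin·Kd·Q + Rmax·c) / (Kd·Q + c),

the exact inverse of the calibration relation below.  F₂ interpolates
between Q (ion-free) and 1 (saturation) so that Q = F₂min/F₂max, and
F₁ = R·F₂; both channels are scaled by a per-cell optical gain
(log-normal, CV 0.2) and carry independent multiplicative Gaussian
noise per frame (σ = 0.01 by default).  Magnesium Green emits one
monotone-saturating channel.  Photobleaching is off by default but
available as an exponential rate.

Ground-truth calibration constants are fixture choices with realistic
dynamic ranges (Mag-fura2: Rmin 0.25, Rmax 4.2, Q 0.93; SBFI: Rmin 0.2,
Rmax 3.6, Q 0.9).  The Q ∈ (0, 1] convention is kept throughout; the
algebra is valid for any positive Q.

Cell-to-cell variability is a log-normal factor on `Vmax`
(unit mean, CV 0.10 by default).  Paired-probe cohorts observe the
*same* simulated trajectory with both SBFI and Mag-fura2 — the
synthetic analogue of parallel dye loadings, chosen so the
stoichiometry statistic is not diluted by across-dye expression
differences that separate cohorts would add.

What the generator does *not* emulate: spatial structure (no pixels or
segmentation), autofluorescence background, probe buffering of the
reported ion, dye leakage and compartmentalization, and correlated
(shared-illumination) noise.  Passing tests therefore validate the
quantification chain, not the behaviour of these real-data nuisances.

## Calibration stage

For dual-excitation probes, concentrations come from the standard
in-situ relation

    c = Kd · Q · (R − Rmin) / (Rmax − R)

with Rmin, Rmax and Q = F₂min/F₂max estimated per cell from the means
of the last k = 3 samples of the two ionophore plateaus, and Kd from
the probe lookup.  Rmax ≤ Rmin flags a failed calibration.  Inversion
handling at the edges is a package convention: R ≤ Rmin maps to 0 mM
(flagged); R within ε = 0.02·(Rmax − Rmin) of Rmax is clamped to the
ε boundary (flagged); R beyond Rmax + ε raises, signalling probe
saturation or a misfit calibration.  Samples on a segment boundary
belong to the later segment.  Single-wavelength traces are reported as
F/F₀ over the pre-depletion baseline instead of concentrations.

Averaging is hierarchical when experiment labels are present: cells are
averaged within each experiment, then the grand mean and s.e.m. are
taken across experiment means, so experiments with unequal cell counts
weigh equally.

## Quantification

The initial velocity V₀ is the two-point difference quotient of the
calibrated concentration between the depletion onset and 20 s later
(one sampling interval), in mM·min⁻¹, signed so Mg²⁺ efflux and Na⁺
influx are positive.  It is deliberately not a regression slope: the
20 s window contains exactly two samples.

The transporter-dependent flux ratio subtracts mock-cohort velocities
in both numerator and denominator,

    ratio = (V₀(Na)ₑₓₚ − V₀(Na)ctl) / (V₀(Mg)ₑₓₚ − V₀(Mg)ctl),

aggregated by default as the ratio of experiment-mean velocities over
6 experiments (mean-of-ratios is available).  A non-positive
denominator raises: without transporter-dependent Mg²⁺ efflux the ratio
is undefined.  The electroneutrality check reports `ratio − 2`
elementary charges per extruded Mg²⁺.  For an ideal 2:1 exchanger the
control subtraction cancels every background flux exactly and the
noiseless ratio is 2; with the default noise the measured ratio
scatters around ≈ 2.0 with an s.d. near 0.1, consistent with (and not
distinguishable from) the 2.14:1 bench estimate it emulates.  The
residual excess above 2 seen at the bench would require a Na⁺ entry
route correlated with transporter expression, which this generator
deliberately does not include.

Hill analysis fits V₀(Mg) against the depletion-buffer Na⁺ level with
V = Vmax·Sⁿ/(K_Aⁿ + Sⁿ) by multi-start nonlinear least squares: 25
starts on a 5×5 log-grid (K_A ∈ [1, 300] mM, n ∈ [0.5, 4]), Vmax
initialized at the curve maximum, K_A optimized on a log scale, bounds
n ∈ [0.5, 4], tolerances 10⁻¹⁴, ties broken by lower RSS then lower n.
Standard errors come from the Gauss–Newton curvature at the optimum.
Fits with fewer than 4 distinct levels, an all-zero curve, or no
converged start are refused rather than reported.

## Fixture parameters

The kinetics are conventions — the assays constrain the Hill exponent
(1.90) much more tightly than the remaining constants — selected once
so the shipped fixtures behave like the experiments they emulate and
the quantification recovers the generating values at the default noise:

| parameter | default | note |
| --- | --- | --- |
| Vmax efflux | 6.0 mM·min⁻¹ | near-complete extrusion within ~1–2 min |
| K_A (Na⁺) | 30 mM | titration series spans 0.3–4.6 × K_A |
| Hill n | 1.90 | generating value of the titration fixture |
| Km (Mg²⁺) | 0.6 mM | keeps the 0–20 s window quasi-linear |
| stoich | 2 | electroneutral exchange |
| p_mg channel | 0.10 min⁻¹ | 40 mM Mg²⁺ re-addition outpaces extrusion |
| p_na leak, pump | 0.002 min⁻¹ | small; cancel under control subtraction |
| loaded state | 3.0 mM Mg²⁺ᵢ, 10 mM Na⁺ᵢ | after 40 mM Mg²⁺ loading |
| unloaded state | 0.8 mM Mg²⁺ᵢ | resting free Mg²⁺ |

Problem sizes of the shipped fixtures: stoichiometry, 6 experiments ×
10 cells × expressing/mock cohorts with paired probes; titration,
6 Na⁺ levels × 3 experiments × 10 cells; four-phase protocol, 10 cells
per condition.  These match the cohort sizes of the assays being
emulated and keep any fixture run in the low seconds.

## Known limitations

* The exchanger rate law is phenomenological; K_A, Vmax and Km are
  identifiable only as effective constants of this form.
* Ratio inversion amplifies frame noise where the probe nears
  saturation; at [Mg²⁺]ᵢ ≈ 2 × Kd the per-frame concentration noise is
  ≈ 3 % and dominates the scatter of two-point initial velocities and
  hence of fitted Hill exponents (s.d. ≈ 0.1 at the default fixture).
* Control subtraction removes only cohort-symmetric backgrounds; any
  expression-correlated leak would bias the flux ratio and is outside
  the model.
* No background subtraction stage: synthetic traces carry no
  autofluorescence.  Real data would need one upstream of
  `compute_ratio`; the trace containers accept such preprocessed input.
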