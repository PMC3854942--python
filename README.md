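# magflux

Simulation and quantification of Na⁺-coupled Mg²⁺ extrusion imaging
assays.

Epithelial Mg²⁺ absorption requires basolateral extrusion against the
membrane potential, carried by Na⁺/Mg²⁺ exchangers such as CNNM4.  The
defining bench experiments are time-lapse fluorescence assays in
cultured cells: load cells with Mg²⁺ in a 40 mM Mg²⁺ buffer, switch to
an Mg²⁺-free buffer, and watch intracellular Mg²⁺ fall (Mag-fura2 or
Magnesium Green) while intracellular Na⁺ rises (SBFI).  Three numbers
summarize the transporter: the Na⁺/Mg²⁺ flux ratio (2 for an
electroneutral 2:1 exchanger), the Hill coefficient of the Na⁺
dependence (≈ 1.9, two Na⁺ sites), and the predicted membrane current
(zero if electroneutral).

`magflux` is aimed at people building or validating such quantification
pipelines.  It provides, as a tested library plus CLI:

* a mechanistic whole-cell generator — two-state ODE (free [Mg²⁺]ᵢ,
  [Na⁺]ᵢ) with Hill-activated exchange, reverse mode, channel leak,
  Na⁺ pump — observed through realistic probe models with in-situ
  ionophore calibration episodes and per-frame noise;
* the quantification chain used at the bench: excitation-ratio
  calibration c = K_d·Q·(R − Rmin)/(Rmax − R), fixed-window initial
  velocities V₀ over the first 20 s after depletion, the
  control-subtracted flux ratio
  (V₀(Na)ₑₓₚ − V₀(Na)ctl)/(V₀(Mg)ₑₓₚ − V₀(Mg)ctl), Na⁺ titration
  curves and multi-start Hill fits V = Vmax·Sⁿ/(K_Aⁿ + Sⁿ).

Because the generator's ground truth is known, every stage is testable
by parameter recovery.  See `docs/methods.md` for the model and all
defaults.

## Worked example

```python
from magflux.pipelines import run_stoichiometry, run_titration

out = run_stoichiometry(seed=20131205)   # 6 experiments x 10 cells, WT + mock
r = out["result"]
print(f"flux ratio       : {r.ratio:.3f} (n = {r.n_experiments} experiments)")
print(f"V0(Na) expressing: {r.v0_na_expressing:.3f} mM/min   control: {r.v0_na_control:.3f}")
print(f"V0(Mg) expressing: {r.v0_mg_expressing:.3f} mM/min   control: {r.v0_mg_control:.3f}")
print(f"net charge per Mg: {out['net_charge_per_mg']:+.3f} e")

fit = run_titration(seed=20131205)["fit"]  # 6 Na+ levels x 3 experiments
print(f"Hill fit         : Vmax {fit.vmax:.2f} mM/min, K_A {fit.ka:.1f} mM, "
      f"n {fit.n:.2f} +/- {fit.se_n:.2f}")
```

prints

```
flux ratio       : 2.057 (n = 6 experiments)
V0(Na) expressing: 8.802 mM/min   control: 0.334
V0(Mg) expressing: 4.169 mM/min   control: 0.052
net charge per Mg: +0.057 e
Hill fit         : Vmax 4.41 mM/min, K_A 28.4 mM, n 1.84 +/- 0.09
```

Reading: each extruded Mg²⁺ is accompanied by ≈ 2 Na⁺ entering
(electroneutral within the noise of the assay — the per-cycle net
charge is 0.06 e), and Mg²⁺ efflux depends on extracellular Na⁺ with
apparent cooperativity n ≈ 1.9, recovering the generator's ground
truth of 1.90 from noisy traces.

The same experiments run from a shell:

```sh
magflux simulate --preset stoichiometry --seed 20131205 --out ds/
magflux analyze ds/ --out results/
magflux report results/results.yaml --out summary/
```

`simulate` writes a tidy trace table (CSV), the protocol schedules
(YAML) and a ground-truth manifest; `analyze` writes `results.yaml`
plus per-experiment V₀ tables; `report` builds condition-comparison
tables (and an overlay figure with `--plot`).  Config errors exit 2,
data errors 3, numeric failures 4.

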