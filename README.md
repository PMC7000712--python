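# ktau — kinetic efficacy and biased-agonism analysis for GPCR biosensor time courses

`ktau` quantifies agonist efficacy from fluorescent-biosensor plate-reader
kinetics as the **initial rate of signaling or arrestin recruitment**,
k<sub>τ</sub> (normalized fluorescence units per minute), and quantifies
**kinetic biased agonism** as ratios of reference-normalized k<sub>τ</sub>
values between pathways. It is aimed at pharmacologists analyzing
genetically encoded sensor assays (arrestin recruitment, DAG, Ca²⁺, cAMP)
who want drug parameters that do not depend on the time point at which an
endpoint assay happens to be read.

## The model

Arrestin (N) binds the agonist-occupied receptor (RA) in a bimolecular step
rate-limited by receptor phosphorylation:

    RA + N  ⇌(k_N / k_−N)  NRA

With ligand binding at equilibrium and receptor (or arrestin) in excess, the
ternary complex follows an association exponential

    [NRA](t) = (ρ_A · k_τ / k_obs) · (1 − e^(−k_obs · t)),
    k_obs = ρ_A · C + k_−N,        ρ_A = [A]ⁿ / (K_Aⁿ + [A]ⁿ)

where k<sub>τ</sub> = [N]<sub>TOT</sub>[R]<sub>TOT</sub>k<sub>N</sub> is the
initial recruitment rate — the kinetic efficacy parameter. The key identity

    Plateau × k_obs = ρ_A · k_τ

means k<sub>τ</sub> is read directly off a routine curve fit: at a saturating
agonist concentration, Plateau × k<sub>obs</sub> = k<sub>τ</sub>. Transient
G-protein signals (DAG, Ca²⁺) follow a rise-and-fall biexponential
C/(k₁−k₂)·(e^(−k₂t) − e^(−k₁t)) whose initial slope C is the same
k<sub>τ</sub> parameter on that pathway, so efficacy is comparable across
pathways with different curve shapes. Bias for ligand L between pathways A
and B is then

    bias ratio = (k_τ^A(L) / k_τ^A(ref)) / (k_τ^B(L) / k_τ^B(ref))

which is invariant to sensor brightness and equals 1 for the reference.

## Worked example

Generate a synthetic saturating-concentration arrestin experiment (three
replicate wells, 9-s reads, 3% multiplicative noise) with known ground truth
(k<sub>τ</sub> = 0.41 NFU·min⁻¹, half-time 45 s), then run the full
single-concentration workflow:

```python
from ktau import PlateauAssociation, generate_arrestin_plate, half_life, ktau_single_conc
from ktau.qc import preprocess
from ktau.simulate import builtin_fixtures

scenario = builtin_fixtures()["angii-arrestin-saturating"]
traces = generate_arrestin_plate(scenario)          # raw downward-sensor wells
curves = [preprocess(tr) for tr in traces]          # ΔF/F then 1 − ΔF/F
fit = PlateauAssociation(curves).fit()              # piecewise baseline + association
print(fit.summary())
est = ktau_single_conc(fit, conc=3.2e-5)
print(f"k_tau = {est.k_tau:.3f} ± {est.se:.3f} NFU/min, "
      f"t1/2 = {half_life(fit.params['k']):.1f} s")
```

Output:

```
PlateauAssociation fit
  n points: 423   R^2: 0.97455   nfev: 30
       param         value       std err
          y0   8.48344e-11      0.004086
     plateau      0.448796      0.001055
           k      0.923896       0.02449
          x0       1.00224       0.02116
k_tau = 0.415 ± 0.011 NFU/min, t1/2 = 45.0 s
```

The fitted onset `x0` absorbs the well-to-well addition-time jitter; the
plateau (0.449) times the rate constant (0.924 min⁻¹) recovers the generating
initial rate 0.41 NFU·min⁻¹ within its standard error, and the half-time
60·ln2/k comes back at 45 s. The same objects drive the
concentration-response route (`ktau_dose_response`, which also returns the
ligand affinity K_A as the L50 of the Plateau×k_obs sigmoid), the global fit
(`ktau_global`), rise-and-fall pathways (`RiseFall`, `ktau_risefall`) and the
bias table (`build_bias_table`).

The same workflows are scriptable from the shell:

```bash
ktau simulate --fixture angii-arrestin-saturating --out plate.csv
ktau ktau plate.csv --method single-conc --out ktau.json
ktau qc plate.csv --out qc.json
```

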