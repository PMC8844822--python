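# nadasekin

Kinetic analysis toolkit for multifunctional NAD(P) glycohydrolases —
enzymes such as CD38, *Aplysia* ADP-ribosyl cyclase and SARM1 that consume
NAD or NADP and partition a common ADP-ribosyl intermediate into hydrolysis
(ADPR), cyclization (cADPR) and base-exchange (transglycosidation) products.
It is written for enzymologists who measure initial rates and multi-analyte
progress curves (typically by HPLC) and need the full analysis chain:
substrate-inhibition rate laws, multi-product activity accounting,
inhibition and allosteric-competition fitting, and seeded synthetic data to
validate every step.

## Models

All concentrations are in μM and specific rates in mU per mg protein
(1 U = 1 μmol/min). Five steady-state laws cover the repertoire:

1. Michaelis–Menten hyperbola
   `v = Vmax·S / (Km + S)` — CD38 and the cyclase;
2. catalytic-site (uncompetitive) substrate inhibition
   `v = Vmax·S / (Km + S·(1 + S/Kis))` — the SAM-TIR fragment of SARM1;
3. dual-site substrate inhibition, adding an allosteric (ARM-site) factor
   `v = Vmax·S / ((Km + S·(1 + S/Kis))·(1 + S/Kia))` — full-length SARM1;
4. one-site dose response `activity = 1 / (1 + I/IC50)`;
5. multi-site mixed-type inhibition
   `v = Vmax·S / (Km·(1 + (I/Ki)^n) + S·(1 + (I/(a·Ki))^n))`,
   where `a` distinguishes competitive (a → ∞), noncompetitive (a = 1) and
   mixed (otherwise) inhibition and `n` counts inhibitor molecules bound.

Inhibition constants that exceed the data's reach are *censored* and
reported as "> 8000 μM" rather than as a number. Fits are unweighted least
squares on untransformed rates with a deterministic multistart;
Lineweaver–Burk transforms and their secondary replots are diagnostics only.
The package also converts crude specific activities to turnover numbers
(`kcat = Vmax·M/(60·purity)` with M in kg/mol) and catalytic efficiencies
`kcat/Km` in M⁻¹s⁻¹, partitions progress-curve activities into branch
fractions with a mass-balance check, and runs the NMN-titration competition
analysis (regression of apparent `Kia` and curve maxima on effector level).

## Worked example

Simulate one noisy NAD kinetic experiment for the full-length enzyme
(truth: Km 30.3 μM, Vmax 22.4 mU/mg, allosteric Kia 324 μM, 5% noise),
refit it, and locate the substrate optimum:

```python
import nadasekin as nk

cfg = nk.SimulationConfig(model="eq3",
                          params={"Km": 30.3, "Vmax": 22.4, "Kia": 324.0},
                          cv=0.05, seed=42)
fit = nk.fit_rate_model(nk.generate_initial_rates(cfg), "eq3")
s_opt, v_opt = nk.curve_maximum(fit.to_parameters())
kcat = nk.kcat_from_specific_activity(fit.params["Vmax"], nk.FULL_LENGTH_FLAG_KDA)
```

prints (via the obvious formatting):

```
fit: {"Km": 25.6, "Vmax": 20.5, "Kis": "> 8000", "Kia": 355.6}
optimum: S_opt = 95.4 uM, V_opt = 12.76 mU/mg
kcat = 0.027 /s, kcat/Km = 1075 /M/s
```

One noisy replicate lands within ~15% of the truth; the catalytic-site
constant is correctly censored (the data carry no evidence for it), the
optimum sits near √(Km·Kia) ≈ 99 μM, and the derived turnover is ~0.03 s⁻¹.
Accounting a noiseless 90:10 hydrolysis:cyclization progress curve returns
fractions 0.90/0.10 and the specific activity implied by the consumption law:

```python
scheme = nk.BranchingScheme(model="eq3",
                            params={"Km": 30.3, "Vmax": 22.4, "Kia": 324.0},
                            f_hydrolysis=0.9, f_cyclization=0.1,
                            protein_conc=100.0)
tc, _ = nk.simulate_time_course(scheme, S0=250.0, duration=30.0)
```

The same stages are scriptable through the `nadasekin` CLI
(`simulate`, `fixtures`, `account`, `fit`, `ic50`, `inhibition`, `compete`,
`recover`), each emitting a JSON report that embeds its full configuration
and seed.

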