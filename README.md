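# eprnano

Membrane nanodomain analysis from nitroxide spin-probe EPR spectra.

Cell plasma membranes are laterally heterogeneous on the nanometre
scale: ordered, cholesterol-rich (raft-like) regions coexist with fluid
disordered ones. A lipophilic nitroxide probe (e.g. MeFASL(10,3))
partitioned into the membrane reports this heterogeneity through its
X-band EPR lineshape, which is a superposition of spectral components —
one per nanodomain type, each described by an order parameter *S*, a
rotational correlation time *τc*, polarity corrections *pA*, *pg*, a
residual width *W*, and a population fraction *d*. `eprnano` implements
the full analysis chain for such spectra:

1. **Forward model** — powder-averaged first-derivative lineshapes for
   fast-but-restricted (wobble-in-cone) probe motion, with motional
   broadening `W + κ τc Var_cone[B_res]`;
2. **HEO fitting** — hybrid evolutionary optimization: a real-coded
   genetic algorithm followed by Nelder–Mead simplex refinement,
   repeated over many independent seeded runs;
3. **GHOST condensation** — χ² and density filtering of the multi-run
   solution cloud, slice-wise group detection along *S*, and per-group
   means, errors and proportions;
4. **Condition statistics** — rank-matched domain comparison across
   experimental conditions as relative changes with Student's t-tests.

Because raw cell spectra for this kind of experiment are rarely
deposited, the package ships a first-class synthetic-data module with
presets for pituitary gonadotrope (αT3-1/αT4) and HEK-293-derived cell
lines; the intermediate-domain order parameters of the two
receptor-expressing presets (S = 0.37 and 0.41) are published values
planted as ground truth, all other preset numbers are documented
package defaults.

## Worked example

```python
from eprnano import (SpectralModel, NoiseModel, generate, make_preset,
                     HeoConfig, GhostConfig)

preset = make_preset("aT3")                       # three planted domains
spectrum = generate(preset, NoiseModel(snr=50, seed=11))

model = SpectralModel(spectrum, k=3)
results = model.fit_multirun(n_runs=50, base_seed=11000)
ghost = results.condense()
print(ghost.summary().to_string(index=False,
      columns=["domain", "n_members", "S", "S_se", "tau_c_ns",
               "proportion_pct"], float_format=lambda v: f"{v:.3f}"))
```

Output (about seven minutes on one core):

```
 domain  n_members     S  S_se  tau_c_ns  proportion_pct
      1         25 0.626 0.000     2.554          43.330
      2         25 0.369 0.000     0.853          35.084
      3         25 0.120 0.000     0.521          21.587
```

Three domain groups emerge from the 50-run solution cloud, ordered by
decreasing order parameter: an ordered raft-like domain (S ≈ 0.63,
slow motion, ~44% of the probe population), an intermediate-order
domain whose mean S ≈ 0.37 recovers the planted published value, and a
fluid domain (S ≈ 0.12). `S_se` is the between-run standard error of
the group mean — near zero here because every retained run converged to
the same solution. `ghost.plot_diagram("S-tau_c")` renders the
corresponding GHOST diagram (solution points colored by the remaining
parameters, red dots at group means).

A command-line interface mirrors the library:

```bash
eprnano synth --preset aT3 --snr 50 --seed 7 --out spectrum.txt
eprnano fit --spectrum spectrum.txt --components 3 --runs 200 --seed 1 --out cloud.json
eprnano ghost --cloud cloud.json --out groups.json --diagrams out/
eprnano compare --cond g_c1.json --cond g_c2.json --ctrl g_k1.json --ctrl g_k2.json --out table.csv
eprnano run --config pipeline.yaml
```

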