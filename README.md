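# riboflex

Quantitative analysis of riboswitch aptamer conformational dynamics from
solution NMR, small-angle X-ray scattering and room-temperature
crystallographic data — built around the adenine-riboswitch aptamer
(rA71, residues 13–84), whose P1 "switching" helix is flexible in the
ligand-free state and rigidifies on adenine binding.

The package covers every quantitative stage of such a study and ships a
seeded synthetic-data generator so the whole pipeline is testable offline:

| module       | what it computes |
|--------------|------------------|
| `relaxation` | R1 and R1ρ from mono-exponential peak-height decays; R2 from R1ρ via the tilt angle; hetNOE with propagated errors; R2/R1 and R2·R1 summaries with k·SD outlier exclusion |
| `dispersion` | R2eff from constant-time CPMG intensities; two-site exchange fits (individual / segmental / global) across one or two fields |
| `csp`        | composite chemical-shift perturbations Δδ<sub>comp</sub> = √(Δδ<sub>H</sub>² + (Δδ<sub>N</sub>/6.5)²) with threshold flagging |
| `guinier`    | radius of gyration from ln I(q) vs q² with the iterative qR<sub>g</sub> < 1.3 window |
| `bfactor`    | occupancy-weighted per-residue, per-region and differential B-factors from PDB/mmCIF files |
| `kinetics`   | forward simulation of the four-state binding scheme apo1 ⇌ apo2 + ade ⇌ IB·ade ⇌ B·ade |
| `synthdata`  | seeded generators for every input type |
| `tablesio`   | TSV/JSON I/O and the `riboflex` command line |

## The central model

Micro-to-millisecond conformational exchange is quantified by fitting
CPMG relaxation-dispersion profiles to the two-site fast-exchange model

```
R2(1/τcp) = R2⁰ + Rex · [1 − 2·tanh(kex·τcp/2) / (kex·τcp)],    Rex = pa·pb·Δω²/kex
```

where kex is the sum of the forward and reverse rate constants, R2⁰ the
exchange-free transverse rate, and τcp the delay between refocusing
pulses (by default the listed ν<sub>cpmg</sub> values are read as the
pulsing rate 1/τcp; the half-cycle convention is selectable).  The
populations and shift difference enter only through Rex, so only the
composite amplitude is reported.  In grouped fits kex is shared across
residues and spectrometer fields, R2⁰ is free per (residue, field), and
Rex scales with the squared field ratio.  For fixed kex the model is
linear in all remaining parameters, so the fit profiles χ²(kex) by exact
weighted linear solves and minimizes it in one dimension; uncertainties
come from seeded Monte-Carlo resampling.

## Worked example

```python
import numpy as np
from riboflex import dispersion, synthdata, guinier, kinetics

# two residues sharing one exchange process, measured at 600 and 850 MHz
truth = {"kex": 319.0, "rex": {14: 3.0, 57: 1.8}, "r2_0": {14: 20.0, 57: 22.5}}
profiles = synthdata.gen_dispersion(truth, fields=(600.0, 850.0),
                                    noise_sd=0.3, seed=11)
fit = dispersion.fit_dispersion(profiles, scope="global", mc_iters=200, seed=11)
print(f"kex = {fit.kex:.0f} +/- {fit.sigma_kex:.0f} s^-1 "
      f"(95% CI {fit.kex_ci95[0]:.0f}-{fit.kex_ci95[1]:.0f})")
# kex = 276 +/- 57 s^-1 (95% CI 167-384)

curve = synthdata.gen_guinier_curve(23.8, I0=1000.0, noise_rel=0.01, seed=3)
res = guinier.guinier_fit(curve)
print(f"Rg = {res.Rg:.2f} +/- {res.sigma_Rg:.2f} A "
      f"({res.n_points} points, qRg_max = {res.qRg_max:.2f})")
# Rg = 23.81 +/- 0.10 A (53 points, qRg_max = 1.29)

model = kinetics.KineticModel()   # stopped-flow rate constants
traj = kinetics.simulate_four_state(model, [10.0, 0.0, 50.0, 0.0, 0.0],
                                    np.linspace(0.0, 10.0, 500))
print(f"B.ade at 10 s: {traj['B.ade'][-1]:.2f} uM of 10 uM RNA")
# B.ade at 10 s: 8.29 uM of 10 uM RNA
```

The dispersion fit recovers the generating k<sub>ex</sub> = 319 s⁻¹
within its 95% interval: with only two residues and σ = 0.3 s⁻¹ noise
the exchange rate is genuinely uncertain at the ±20% level, and the
Monte-Carlo interval reflects that honestly.  The Guinier fit trims the
curve to the 53 lowest-q points satisfying q·R̂g < 1.3 and recovers the
radius to 0.1 Å.  The kinetics run shows adenine driving most of the
RNA into the docked bound state within seconds.

Each module is also reachable from the shell:

```
riboflex cpmg --intensities cpmg.tsv --scope global --out fit/
riboflex guinier --curve saxs.dat
riboflex bfactor --pdb structure.pdb --chain A
riboflex kinetics --t-end 10 --out trajectory.tsv
```

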