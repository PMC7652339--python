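# killcurve

Kinetic analysis of live-cell imaging killing assays for engineered T cells.

Co-culturing receptor-engineered T cells (TCR- or CAR-transduced) with
peptide-loaded target cells under a scanning microscope yields, per well and
time point, three measurements: the live effector count (green vital dye,
red-negative), the red pixel area of dead/dying cells (Annexin V / propidium
iodide), and the phase-contrast pixel area occupied by target cells. From
these, `killcurve` disentangles **antigen-dependent T-cell proliferation**
from **target-cell cytotoxicity** over time and summarises each construct and
effector:target (E:T) ratio by dose-response **sensitivity (EC50)** and
**magnitude (Emax)** — the quantities used to rank-order receptor candidates.

It is written for assay developers and computational biologists who run (or
model) 384-well co-culture titrations and want a transparent, fully testable
alternative to opaque instrument software.

## Readouts

With `E_live(t, c)` the effector count at time `t` and peptide concentration
`c`, `t0 = 2 h` the post-settling reference scan, and all derived series on a
6-hour grid:

| readout | definition |
|---|---|
| fold proliferation | `P(t,c) = E_live(t,c) / E_live(t0,c)` |
| total death (%) | `T_dead(t,c) = 100 × Σ red px / Σ phase px` |
| specific killing | `K(t,c) = T_dead(t,c) / T_dead(t,0)` |
| killing per T cell | `S(t,c) = [T_dead(t,c)/E_live(t−6,c)] / [T_dead(t,0)/E_live(t−6,0)]` |
| proliferation rate | `P′(t,c) = 4 × [E_live(t,c) − E_live(t−6,c)] / E_live(t−6,c)` (per day) |
| kill rate | `K′(t,c) = [K(t,c) − K(t−6,c)] / E_live(t−6,c) / 6 h` |

Normalising by the 0-dose control removes nonspecific/allo-reactive killing;
the 6 h lag attributes observed death to the effectors present one interval
earlier. Dose-responses are read at the peak times of each readout
(proliferation at ~72 h, killing at ~48 h, rates at their per-dose maximum in
the 30–72 h window) and fitted with a four-parameter logistic
`r(c) = bottom + (top − bottom) / (1 + (EC50/c)^h)` in log-dose; `Emax` is
the fitted top plateau.

The package ships a **stochastic co-culture simulator** (dose-dependent
killing and proliferation hazards, effector-density-dependent engagement,
resource coupling, counting noise) and a **synthetic frame renderer** with
ground-truth label maps, so every stage — segmentation, kinetics, fitting —
is testable without instrument data.

## Worked example

```bash
cat > example.yaml <<EOF
simulation:
  effector_to_target_ratios: [3.0, 1.0]
  scan_interval: 2
plate:
  replicates: 2
EOF
killcurve run-all --config example.yaml --seed 11 --out run/
killcurve report --run-dir run/
```

which prints (abridged):

```
construct et_ratio            readout  ec50_um       emax          emax_units hill_slope  converged                              flags
  SIM-TCR      3:1      proliferation 0.002016      3.605       fold increase       2.13       True
  SIM-TCR      3:1   specific_killing  0.04117      11.61          per T cell       1.67       True
  SIM-TCR      3:1 proliferation_rate 0.001767      50.44               %/day       2.04       True
  SIM-TCR      3:1          kill_rate 0.002496  4.209e-06 per T cell per hour       1.06       True no_dose_dependence;ec50_unreliable
  SIM-TCR      1:1      proliferation 0.002172        3.7       fold increase        1.8       True
  SIM-TCR      1:1   specific_killing  0.04956      9.675          per T cell       1.61       True
```

Reading the table: the simulated construct kills with an EC50 of
~0.04–0.05 μM (the generative Hill EC50 is 0.05 μM) and proliferates with an
EC50 ~20-fold lower, mirroring the greater sensitivity of proliferation;
per-T-cell killing Emax falls from 11.6 at E:T 3:1 to 9.7 at 1:1 — at lower
effector density each target is engaged less often while the surviving
targets keep regrowing, so the dose-normalised kill magnitude drops even on a
per-effector basis; a readout whose response
carries no dose signal is flagged `no_dose_dependence` rather than reported
as a spurious EC50. Data-quality flags raised during kinetics (e.g. clamped
zero-dose controls) are appended verbatim to `summary.txt` and counted in
`manifest.json`.

The run directory contains `platemap.csv`, `wells.csv` (raw series),
`truth.json` (latent ground truth, simulation modes), `profiles.csv` (all six
readouts per dose × grid time), `fits/*.json`, `summary.csv`/`summary.txt`,
a `dose_response.png` overview figure, `manifest.json` and `run.log`. Three entry modes cover the pipeline stages:
`from_simulation` (emitted counts), `from_images` (render synthetic frames,
re-quantify them with the built-in segmenter), and `from_counts` (your own
per-well CSV plus a plate map).

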