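# krigdoe

Kriging-assisted design of experiments for closed-loop optimization of a
phototrophic culture medium toward maximal volumetric lipid productivity.

The package plans the four experimental rounds of a microtiter-plate
campaign, analyses the resulting plate readouts, and proposes the next
experiments:

1. **Screening** — a regular two-level fractional factorial over the nine
   free medium variables (component reduction: clustering of the six trace
   elements, stock-solution ties, fixed components), sized so that all main
   effects and every two-factor interaction with MgSO4 are estimable free of
   mutual aliasing (32 runs + 5 reference wells = 37).
2. **Confirmation** — a 2^5 full factorial over the retained factors
   (32 runs + 5 references).
3. **Nested refinement** — stacked 2^3 cubes over three MgSO4 levels with a
   half-range inner cube, center points and maximin edge points
   (35 runs + 4 references = 39).
4. **Expected-Improvement refinement** — 12 proposals drawn from a
   Delayed-Rejection Adaptive-Metropolis chain targeting a density
   proportional to EI(x), plus 23 uniform space-filling runs + 4 references.

An ordinary-Kriging surrogate (anisotropic squared-exponential correlation,
profiled trend and variance, ML-estimated correlation lengths and nugget) is
refit after every round; component effects are screened with t tests against
an error variance pooled from fit residuals and reference replicates.

A parametric ground-truth surface with seeded measurement noise emulates the
cultivation platform (interior optimum at MgSO4 3.25, CaCl2 1.25, trace 2.5,
NaNO3 0.45 xRef; optimum/baseline ratio 3.03), so the entire loop is testable
in silico.

## Command line

```bash
# plan a campaign round (written as run/plate/well CSV)
krigdoe design --round 1 --out design.csv

# estimate component effects from plate results
krigdoe effects --design design.csv --data results.csv \
    --normalize --interactions MgSO4:* --out effects.csv

# fit the Kriging surrogate and slice it
krigdoe fit --data results.csv --out model.txt
krigdoe surface --model model.txt --axes MgSO4,NaNO3 \
    --fixed CaCl2=1.0,trace=1.0 --out grid.csv

# EI-guided batch proposal (DRAM chain, 10000 draws / 1000 burn-in)
krigdoe propose --model model.txt --data results.csv --n 12 --seed 1 \
    --out proposals.csv

# full in-silico campaign against the synthetic surface
krigdoe simulate --seed 1 --out campaign_out/
```

All concentrations are handled in xRef units (multiples of the reference
medium concentration). Models and surfaces serialize to a flat `key = value`
text format with embedded CSV blocks; designs and observations are plain CSV.

## Package layout

- `krigdoe.designs` — factor spaces, factorial/fractional/nested design
  generators, reference replicates, plate math, pipetting-grid snapping
- `krigdoe.effects` — observation sets, reference normalization, effect
  estimation and significance screening
- `krigdoe.kriging` — ordinary-Kriging fit/predict/grid evaluation and
  flat-text model serialization
- `krigdoe.ei_design` — Expected Improvement, DRAM sampling, batch selection,
  uniform space filling
- `krigdoe.synthetic_data` — ground-truth surface, in-silico evaluation,
  fixture campaign
- `krigdoe.campaign` — four-round orchestration, improvement-factor
  prediction, reporting; `krigdoe.cli` — command-line interface
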