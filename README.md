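# oenoflux

Multi-phase constraint-based analysis of *Oenococcus oeni* batch
fermentations under ethanol stress: from time-course concentrations to
per-phase specific rates, an extended stoichiometric system linking growth
phases through intracellular accumulation reactions, maintenance-ATP (NGAM)
estimation with sensitivity analysis, ATP / NAD(P)H / proton accounting,
elementary-flux-mode substrate-product mapping, and hit-and-run sampling of
the constrained flux space.

The package ships a reduced central-carbon network of *O. oeni* (heterolactic
phosphoketolase pathway, fructose reduction to mannitol, erythritol
formation, citrate degradation, malolactic reaction, amino-acid degradation,
F0F1-ATPase, maintenance and biomass reactions, with explicit ATP, NAD(P)H
and proton species) and a synthetic-data generator that produces batch
cultures with a stoichiometrically consistent, known ground truth, so the
entire pipeline is testable offline.

## Layout

| module | contents |
| --- | --- |
| `oenoflux.network` | network data model, JSON / TSV / SBML I/O, validation |
| `oenoflux.reduced_model` | the packaged reduced *O. oeni* network |
| `oenoflux.rates` | OD600 calibration, phase segmentation, per-phase specific rates |
| `oenoflux.extended` | 3-phase stacked system with accumulation reactions, spans via FVA, per-phase split models |
| `oenoflux.fba` | LP engine: FBA, FVA, NGAM grid estimation, NGAM sensitivity |
| `oenoflux.energetics` | ATP-route, redox and proton accounting with stoichiometric audits |
| `oenoflux.efm` | exact elementary-flux-mode enumeration and the substrate-product table |
| `oenoflux.sampling` | artificial-centering hit-and-run sampler, flexibility statistics |
| `oenoflux.synth` | synthetic batch-culture generator with LP-witness ground truth |
| `oenoflux.pipeline` | end-to-end orchestration and machine-readable reports |

## Command line

```bash
oenoflux model info                         # packaged network summary
oenoflux synth --ethanol 12 --seed 42 --out tc.tsv
oenoflux rates --input tc.tsv               # per-phase mu and q
oenoflux extend --input tc.tsv              # accumulation spans (extended FVA)
oenoflux fba --out flux.json
oenoflux energetics --flux flux.json
oenoflux efm --table                        # substrate-product mode counts
oenoflux sample --n 5000 --thinning 500 --seed 7
oenoflux run --config run.yaml              # full pipeline
```

A minimal `run.yaml`:

```yaml
ethanol_levels: [0, 3, 6, 9, 12]
tolerance: 0.0
run_efm: true
run_sampling: false
output_dir: out
```

## Library sketch

```python
from oenoflux import (
    load_reduced_oeni_model, default_config, simulate_culture,
    estimate_rates, build_extended_model, apply_experimental_constraints,
    fva_accumulation, split_into_phase_models, estimate_ngam,
)
from oenoflux.pipeline import phase_constraints_from_rates

base = load_reduced_oeni_model()
tc, truth = simulate_culture(default_config(), ethanol_level=9.0, noise_cv=0.0)
rates = estimate_rates(tc)
constraints = phase_constraints_from_rates(rates, tolerance=0.0)
ext = apply_experimental_constraints(build_extended_model(base, 3), constraints)
spans = fva_accumulation(ext)
models = split_into_phase_models(ext, spans)
ngam = estimate_ngam(models[0], constraints[0], rates[0].mu)
```

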