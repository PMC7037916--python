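# duotox

Dual-endpoint toxicity QSAR toolkit for quinolone antibiotics: composite
indexing of green-algae toxicity and bacterial genotoxicity, similarity-index
3D fields on a lattice, NIPALS partial-least-squares modeling with a full
validation battery, contour extraction for substitution guidance, and the
change-rate arithmetic used to screen candidate derivatives.

## What's inside

| Module | Purpose |
| --- | --- |
| `duotox.dataset` | Toxicity/property record types, the packaged 50-compound dataset (endpoints, published composites, 40/10 train–test split), SDF/MOL2/SMILES and CSV readers |
| `duotox.composite` | Comprehensive-index compositing `Z = w1·X1/M1 + w2·X2/M2` with two standard calibrations (shared mean-|pEC50| and per-endpoint means) and a reproduction report against the stored column |
| `duotox.prepare` | ETKDG embedding + MMFF minimization, per-atom field weights (Gasteiger charge, vdW-volume steric, Crippen logP, donor/acceptor flags), maximum-common-substructure template superposition (Kabsch) |
| `duotox.fields` | Gaussian similarity-index fields (S/E/H/D/A) on a regular lattice, variance filtering, block scaling, descriptor assembly, cube/DX export |
| `duotox.qsar` | NIPALS PLS1, leave-one-out q², R²/SEE/F, external r²pred/SEP, per-field contribution percentages, progressive response scrambling (Q², cSDEP, dq²/dr²yy), StDev*Coeff contour masks |
| `duotox.design` | Signed/magnitude change rates, log-level toxicity-change ratios, derivative ranking |
| `duotox.synthetic` | Seeded point-atom molecule generator with planted linear field→activity structure for recovery testing |
| `duotox.pipeline` / `duotox.cli` | End-to-end configured runs and the `duotox` command-line interface |

## CLI

```sh
# composite values for the packaged dataset (or your own CSV via --in)
duotox composite --weights 0.8 0.2 --calibration shared --out table_with_z.csv

# PLS model on descriptor CSVs (columns '<field>_<point>', response 'y')
duotox qsar --train train.csv --test test.csv --components auto --scramble --out model.json

# rank candidate derivatives by composite change rate
duotox screen --parent CIP --candidates candidates.csv --properties props.csv --out report.json

# synthetic aligned set with planted structure
duotox synth --spec spec.yaml --out synth_set/

# full pipeline from a YAML config (synthetic or structure-based mode)
duotox run --config run.yaml
```

A minimal `run.yaml`:

```yaml
seed: 11
mode: synthetic
out_dir: bundle
synthetic: {n_molecules: 30}
fields: {spacing: 7.0, margin: 1.0}
pls: {components: 3, scramble: true}
```

Structure-based runs use `mode: structures` with `toxicity_table: fixture`
(or a CSV path) and `structures_path`/`structures_format` pointing at an
SDF/MOL2/SMILES file whose entry names match the dataset's compound ids;
molecules are aligned to the configured template (default `MOX`).

## Notes on conventions

- Composite reproduction uses the shared-standard calibration
  (M = mean |pEC50| = 2.8752); 48/50 stored rows match exactly at 2 dp,
  49/50 within one unit of the stored last digit, and the remaining row is
  flagged `inconsistent` in the fixture (its stored value disagrees in sign
  with the documented formula).
- Change rates use a signed convention except for total energy and docking
  binding energy, whose stored reference rates count growth in magnitude.
- Progressive scrambling perturbs the response by rank-bin coarsening
  (level 1 = full permutation) and reports Q²/cSDEP interpolated at the
  critical correlation r²yy' = 0.85; the slope is the least-squares slope of
  q² against r²yy'.
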