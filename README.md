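# seqrsa

Searchlight representational similarity analysis (RSA) of history-dependent
neural codes during structured event sequences, plus a synthetic-data
generator that plants each code with known strength so the whole pipeline is
testable end to end without any external data.

The experimental design is a two-schema ("North"/"South") wedding-ritual
task: six rituals arranged in four paths over three analyzed stages, where
the stage-2 ritual is unpredictable and later transitions are deterministic
given the schema. The pipeline computes, per searchlight:

- **schema code** — same-schema minus different-schema pattern similarity,
- **path code** — same-path minus different-path (same schema only;
  cross-schema cells omitted so the contrast is uncorrelated with the
  schema contrast),
- **current ritual code** — within-stage same-ritual minus other-ritual,
- **rotated preceding ritual code** — a "photo-negative" carry-over of the
  previous ritual, detected as especially *low* similarity when a stage-2/3
  template matches the held-out pattern's predecessor/successor,
- **non-rotated preceding/upcoming code** — the sign-flipped rotated
  contrast.

Group maps use one-sample one-tailed t-tests with Benjamini–Hochberg FDR,
plus conjunction masks (significant for both codes) and disjunction masks
(FDR-significant for one code and above a liberal uncorrected threshold for
the other). Per-wedding code strengths in significant regions feed a
within-participant Spearman brain–behavior correlation tested against a
behavior-shuffling permutation null, with JZS Bayes factors (Cauchy scale
0.707) on Fisher-Z-transformed correlations.

## Layout

| module | contents |
| --- | --- |
| `seqrsa.design` | ritual/schema/path graph, schedules, answer keys |
| `seqrsa.simulate` | region layouts, planted-code pattern generator, coupled behavior |
| `seqrsa.rsa` | leave-one-wedding-out templates, Pearson similarities, comparison taxonomy |
| `seqrsa.contrasts` | the five code contrasts, predicted-pattern matrices |
| `seqrsa.searchlight` | searchlight geometry + engine, group t/FDR maps, conjunction/disjunction, paired tests, JZS Bayes factors |
| `seqrsa.behavior` | per-wedding strengths, Spearman + permutation test, behavioral scoring |
| `seqrsa.io` / `seqrsa.cli` | NIfTI/TSV/YAML I/O and the command-line surface |

## CLI

```bash
# write a config
cat > config.yaml <<EOF
generator:
  n_participants: 10
  grid_shape: [20, 20, 20]
  seed: 7
n_perm: 1000
EOF

seqrsa simulate   --config config.yaml --out data/
seqrsa contrasts  --data data/ --out scores.csv
seqrsa searchlight --data data/ --out maps/ --q-thresh 0.05 --p-liberal 0.1 --min-members 63
seqrsa behavior   --data data/ --masks maps/ --out brain_behavior.csv --n-perm 1000 --seed 7
seqrsa report     --out report/
```

`simulate` writes one 4D NIfTI per participant (volumes ordered
wedding-major then stage), an events TSV sidecar per participant, the mask
and region-label NIfTIs, and the behavior TSV. `searchlight` writes per-code
stat maps (NIfTI + tidy CSV), per-code significance masks, the
rotated∧current conjunction mask and both disjunction masks. `behavior`
writes a table of r mean ± SEM, permutation p, and BF-01 per region/code/
measure pairing.

### Comparison-table columns

`seqrsa.rsa.compare_all` returns one row per (participant, held-out
wedding, template cell, held-out stage): `participant`,
`held_out_wedding`, `template_ritual`, `template_schema`, `template_stage`,
`heldout_stage`, `heldout_ritual`, `heldout_schema`, `stage_relation`
(within/across), `path_relation` (1 same path+schema; 2 different path,
same schema; 3 different schema, no ritual match; 4 different schema,
template ritual on the held-out path), `same_schema`, `same_ritual`,
`same_preceding_ritual`, `same_upcoming_ritual`, `template_is_predecessor`,
`template_is_successor`, `similarity` (Pearson r).

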