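# hydroscreen

A tested, reusable pipeline for screening protein hydrolysates as
metal-chelating / radical-scavenging antioxidant candidates:

- **peptide_io** — read/validate/filter MaxQuant-style peptide identification
  tables and protein FASTA databases (3–65 residue window, reverse/contaminant
  removal with a per-reason filter report).
- **quant_stats** — intensity-weighted peptidomic summary statistics per
  sample/fraction: weighted and arithmetic mean length, additive per-residue
  net charge (Asp/Glu −1, Arg/Lys +1, His +0.1), relative molar amino-acid
  abundance on the residue-pool definition, length histograms.
- **antiox_scoring** — attach externally predicted FRS/CHE scores (consumed,
  never computed), threshold aggregation (FRS ≥ 0.43, CHE ≥ 0.30, inclusive),
  ANOVA + Tukey comparison, and exclusive-intersection (UpSet) overlap
  analysis.
- **assay_calcs** — protein content/yield, OPA serine-equivalent and degree of
  hydrolysis (DH%) calculus with calibration-range well exclusion, glycine
  equivalents for SPR analyte quantification.
- **spr_binding** — SPR double referencing, equilibrium-response extraction,
  and 1:1 (Langmuir) binding-model fits (K_D, R_max, SEs) with
  saturation-adequacy flagging (K_D > C_max/2 ⇒ likely underestimate).
- **synthetic** — a synthetic hydrolysate study generator: sequential
  stochastic protease digestion (broad-specificity or Arg/Lys-specific endo
  followed by an endo+exo cocktail) with ground-truth DH, ultrafiltration
  into <1 / 1–3 / 3–5 kDa fractions with imperfect separation, a length- and
  Lys-biased MS observation model, Beta-distributed score tables, Langmuir
  isotherms, and OPA plates.
- **pipeline** — end-to-end orchestration with a pydantic `StudyConfig`;
  identical config + seed produce byte-identical report JSON.

## CLI

```bash
hydroscreen simulate --seed 1 --outdir study/          # emit synthetic inputs
hydroscreen run --seed 1 --outdir results/             # full analysis report
hydroscreen filter --in peptides.tsv --min-len 3 --max-len 65 \
    --out filtered.tsv --report report.json
hydroscreen summarize --in filtered.tsv --out summary.tsv
hydroscreen scores --in filtered.tsv --scores scores.tsv --frs 0.43 --che 0.30 \
    --out agg.tsv
hydroscreen overlap --in filtered.tsv --out upset.csv
hydroscreen dh --plate plate.csv --cal serine.csv --protein-pct samples.json \
    --out table1.tsv
hydroscreen spr-fit --in isotherm.csv --out fit.json
```

`hydroscreen run`/`simulate` also accept `--config study.yaml` with any
`StudyConfig` field.

## File formats

All inputs and outputs are plain text: tab-separated peptide tables
(MaxQuant `peptides.txt` dialect: `Sequence`, `Proteins`, `Reverse`,
`Potential contaminant`, `Intensity <sample>` columns), FASTA, score TSV
(`sequence`/`FRS`/`CHE`), isotherm CSV (`concentration_mM_eq_gly`,
`response_RU`), OPA plate CSV (`sample`, `df`, `replicate`, `absorbance`,
with `blank` rows), calibration CSV (`concentration`, `absorbance`), and
JSON reports.
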