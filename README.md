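# pressc

Discriminate real microRNA precursor hairpins from pseudo hairpins using
**structure-status composition** features and an RBF-SVM.

Every position of an RNA secondary structure is encoded as one of ten
statuses — the four unpaired bases `A C G U` plus six
orientation-distinguished pair statuses `A-U U-A G-C C-G G-U U-G`. From this
encoding the package builds:

- the **structure-status composition vector**: normalized `10^n` n-tuple
  status frequencies extended with `λ` tiered correlation factors (mean
  squared free-energy differences at offsets `1…λ`, using pair energies
  A-U/U-A = −2, G-C/C-G = −3, G-U/U-G = −1, unpaired = 0 kcal/mol) weighted
  by `w` and jointly normalized to sum to 1 (dimension `10^n + λ`);
- the **extended vector**: the above concatenated with the structure MFE, a
  Monte-Carlo randomization-test P-value, and the 64 overlapping
  tri-nucleotide frequencies (dimension `10^n + λ + 66`).

Classification is an RBF-SVM with per-column `[-1, 1]` scaling, evaluated by
jackknife or stratified k-fold cross-validation with Sn/Sp/Acc/MCC and
ROC/AUC, plus the 800-cell `(n, λ, w)` tuning grid
(`n ∈ 1..4, λ ∈ 1..20, w ∈ 0.1..1.0`). Two published optima ship as presets:

| preset     | features | n | λ  | w   | C   | γ    |
|------------|----------|---|----|-----|-----|------|
| `pressc`   | base     | 2 | 13 | 0.5 | 8   | 2⁻⁵  |
| `expressc` | extended | 1 | 17 | 0.2 | 128 | 2⁻⁷  |

## CLI

All commands are subcommands of `pressc` (exit codes: 0 ok, 1 data error,
2 usage error). An end-to-end run on synthetic data:

```sh
pressc simulate --n-pos 200 --n-neg 200 --seed 7 \
    --out-vienna sim.vienna --out-manifest sim.tsv
pressc featurize sim.vienna --preset pressc --labels sim.tsv -o features.tsv
pressc evaluate features.tsv --preset pressc --scheme kfold --k 5
pressc train features.tsv --preset pressc -o model.joblib
pressc predict features.tsv --model model.joblib
```

Other subcommands:

- `fold` — FASTA → Vienna dot-bracket records, via the deterministic
  maximum-base-pairing baseline folder or an external thermodynamic folder
  (`--backend external --folder-cmd "RNAfold --noPS"`). The baseline folder
  is non-thermodynamic (its "MFE" is a pseudo energy from the status
  free-energy table) and exists so the whole pipeline runs without external
  software; production results should use a real folder.
- `gridsearch` — stratified k-fold search over `(n, λ, w) × (C, γ)`.
- `benchmark` — admission filtering of candidate pseudo hairpins (length in
  [51, 137] nt, ≥ 18 base pairs, MFE ≤ −15 kcal/mol, all inclusive),
  optional class balancing and an external CD-HIT-style redundancy
  reduction hook; writes a manifest TSV.
- `simulate` — labeled synthetic hairpins (planted stems) and decoys
  (same sequence construction, interrupted stems) with controllable
  separation.

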