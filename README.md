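# miequiv

Measurement invariance for multi-group confirmatory factor models,
evaluated by **equivalence testing** instead of conventional null-hypothesis
testing, plus a **projection-based comparison of latent means** that does
not require equal intercepts across groups.

The package provides:

- **`miequiv.model_io`** — a `factor =~ indicator + ...` measurement-model
  parser, plain-text moment files (variable-name header, `mean`-labeled row,
  labeled covariance matrix), and moment computation from raw tables with a
  group column.
- **`miequiv.mgsem`** — normal-theory ML fitting of the multi-group factor
  model with mean structure under the invariance-constraint sequence
  (configural → metric → residuals/varfactor and scalar → strong/strict
  variants), chi-square and chi-square-difference statistics with exact
  df accounting, and a closed-form test of equal population covariance
  matrices. Fits use analytic gradients on an unconstrained
  reparameterization (log error variances, Cholesky factor covariances)
  with deterministic restarts.
- **`miequiv.equivalence`** — the T-size calculus: inverting the left-tail
  noncentral chi-square critical value at the observed statistic to get the
  minimum tolerable misspecification ε_t, the corresponding RMSEA_t, and
  df/N-adjusted cutoffs with excellent/close/fair/mediocre/poor labels.
- **`miequiv.projection`** — orthogonal decomposition of each group's mean
  vector into common-score and specific-factor components given a common
  loading matrix, Wald tests of cross-group equality of each component
  (df = (m−1)k and (m−1)(p−k)), the validity index ρ²_c, equivalence-test
  versions of the Wald tests, and within-group bootstrap p-values.
- **`miequiv.simulate`** — a seeded multivariate-normal generator for
  multi-group factor designs with switchable invariance violations
  (loading / intercept / latent-mean / specific-mean shifts) that can be
  calibrated to a target population misfit.
- **`miequiv.cli`** — a command-line pipeline rendering the eight-part
  report (covariance-equality test, chi-square sequence, T-size tables,
  projection Wald tests, validity index, and the three comparison tables).

## Command line

```sh
# full pipeline from a raw table with a group column
miequiv run --model model.txt --data data.csv --group-col group --json out.json

# or from per-group moment files (sizes supplied separately)
miequiv run --model model.txt --moments g1.txt --moments g2.txt --nobs 78,174

# stand-alone T-size calculator
miequiv tsize -t 4.984 --df 3 -n 252 -m 2

# synthetic fixture data
miequiv simulate --model model.txt --n 200,200 --seed 1 --out sim.csv
```

A model file holds one factor per line:

```
AlphabetKnowledge =~ Letter_Name + Letter_Sound
PhonologicalAwareness =~ Blending + Elision
Spelling =~ Real_Words + Pseudo_Words
```

`--output mean|covariance|both` restricts the sequence to the mean or
covariance branch; `--no-projection` drops the projection parts;
`--bootstrap B` adds bootstrap p-values (raw data input only).

## Conventions

- Chi-square scale: `T = (N − m)·F` with `F = Σ_j (n_j/N) F_j` over biased
  (divisor-n) sample covariances; `scale="n"` selects `T = N·F`.
- Moment files are read as (n−1)-based covariances and rescaled internally.
- Identification: first indicator per factor is the marker (loading 1);
  latent means are zero until intercepts are constrained equal, then
  group 1 is the baseline.
- The δ↔ε divisor is N − m for likelihood-ratio and projection Wald
  statistics alike (`divisor="n"` is available on `tsize`).
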