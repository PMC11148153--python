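# smrt

Analysis toolkit for sterile-male-release suppression of sea lamprey
populations. It implements three connected pieces:

- **Adult trap assessment** (`smrt.trap`) — Lincoln–Petersen abundance from
  sterile-male recapture rates, realized sterile:wild-male ratios, and
  viable-egg accounting before/after sterile-male release. A packaged CSV of
  published decade-long trap counts for the Pigeon, Sturgeon, and Maple
  Rivers ships with the package (`smrt.published_trap_csv()`).
- **Hierarchical recruitment model** (`smrt.recruitment`, `smrt.mcmc`) — a
  Bayesian negative-binomial model of age-1 larval recruitment indices,
  `log A = a_s + a'_yr,s − q_s·E`, with year deviations
  `a' ~ Normal(0, σ_a)` and release effort `E` = sterile males released /
  1000 in the spawning year (survey year − 1). Fitting uses an adaptive
  random-walk Metropolis-within-Gibbs sampler with non-centered year
  effects and directional ridge updates; convergence is reported as
  split-R-hat per parameter. The release effect is summarized as percent
  reduction in recruitment, `100·(1 − e^(−qE))`.
- **Synthetic data** (`smrt.simulate`) — seeded generators for trap seasons
  (binomial equal-catchability trapping), viable-egg outcomes, and
  overdispersed larval surveys, bundled into the exact CSV dialects the
  other stages consume, with the generating truth recorded in `truth.json`.

## Command-line interface

```sh
# adult assessment over a trap-season CSV
smrt assess --trap trap_seasons.csv --p-female 0.5 --fecundity 51000 \
    --convention table --out assessment.csv

# generate a seeded synthetic study (CSV bundle + truth.json)
smrt simulate --config sim.yaml --out data/ --seed 1

# fit the recruitment model by MCMC
smrt fit --surveys data/larval_surveys.csv --releases data/releases.csv \
    --chains 4 --iter 5000 --warmup 2000 --seed 1 --out posterior/

# assemble the markdown report
smrt report --assessment assessment.csv --posterior posterior/summary.json \
    --out report.md
```

Every artifact-producing run writes a side-car metadata JSON (package
version, seed, config hash, timestamps). Reports are byte-identical for
identical inputs.

Input formats:

- `trap_seasons.csv`: stream, year, sterile_released, sterile_recaptured,
  wild_captured, wild_males_observed (blank allowed); optional columns
  abundance_est (externally derived abundance), ratio_censored_at,
  ambiguous. Lines starting with `#` are comments.
- `larval_surveys.csv`: stream, year, site, density_per_m2 (age-1 larvae
  per m²). Length records (stream, year, month, site, length_mm, area_m2)
  can be aged with the length-by-month rule via
  `smrt.surveys_from_lengths` and aggregated to site densities.
- `releases.csv`: stream, spawning_year, sterile_released.

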