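# occumix

Hierarchical occupancy / zero-truncated N-mixture modelling for
repeat-count wildlife surveys, aimed at before/after-control-impact
evaluations of habitat restoration on social-group counts.

The model has a two-layer state process — site occupancy
`Z ~ Bernoulli(ψ)` and, given occupancy, group size
`N ~ zero-truncated Poisson(λ)` with log-linear covariate effects and a
site random effect — and a two-layer observation process: whole-group
availability `A ~ Bernoulli(pZ)` and per-bird detection
`Y ~ Binomial(N, dA)`. `p` and `d` are separated by a within-season
repeat-count calibration panel. Variants: `M1` (no site random effect),
`M2` (random effect; the default), `M4` (adds a pre-existing restoration
baseline term), `M6` (adds the linear occupancy model for the
later-colonised stratum).

## What's in the box

| module | role |
|---|---|
| `occumix.data_io` | CSV formats, validation, 2-SD covariate standardization |
| `occumix.synthetic_data` | design-aware simulator (site strata, restored/unrestored split, calibration panel) |
| `occumix.model_core` | distributions, linear predictors, priors, exact per-site marginal likelihood |
| `occumix.inference` | adaptive Metropolis-within-Gibbs sampler (discrete latents marginalized), PSRF, summaries, deviance-based model comparison |
| `occumix.reporting` | scenario predictions (group size at average sites), odds-ratio / multiplicative effect tables, covariate balance checks |
| `occumix.cli` | `simulate` / `fit` / `report` / `recover` / `compare` with manifests |

A compiled (numba, optional) whole-dataset likelihood backs the sampler;
the slow enumeration-based reference in `model_core` is kept as an
independent oracle and the tests assert agreement.

## CLI quick start

```bash
# simulate a full study at the published design (67/50/41 sites + 29x4 panel)
occumix simulate --seed 1 --out-dir scratch/sim

# fit the default variant and summarize
occumix fit --study scratch/sim/study.csv --detection scratch/sim/detection.csv \
    --seed 1 --out-dir scratch/fit --chains 3 --burnin 2000 --samples 30000 \
    --max-count 1000
occumix report --draws scratch/fit/draws.csv --study scratch/sim/study.csv \
    --out-dir scratch/report --max-count 1000

# parameter-recovery experiment (simulate -> fit -> coverage table)
occumix recover --seed 1 --replicates 20 --out-dir scratch/recover \
    --chains 2 --burnin 1000 --samples 10000

# compare variants by posterior mean conditional deviance
occumix compare --study scratch/sim/study.csv --detection scratch/sim/detection.csv \
    --variants M1,M2 --seed 1 --out-dir scratch/compare --max-count 1000
```

Every command writes a `manifest.json` (seed, config, version, dataset
fingerprint) so artifacts are reproducible from the manifest alone.

## Data formats

`study.csv` — one row per site:
`site_id,set,work,dist,tree_1995,tree_2008,y_1995,y_2008,y_2009`, with
`set` in `SET1|SET2|SET3` (detection-history strata), empty cells meaning
*survey not done* (an explicit `0` is an informative zero count). `SET3`
rows carry no `dist`/`tree` covariates. `detection.csv` — one row per
calibration site: `site_id,count_1..count_4`.

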