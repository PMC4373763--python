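# twodedd

Differential display of two-dimensional gel electrophoresis (2DE)
spot-volume tables. Given a spots × gels matrix of stain volumes for
control, knockdown and (optionally) wild-type reference gels, the package:

1. **normalizes** gels to a common total volume and summarizes per-gel
   log-volume distributions (box-plot style QC with outlier-gel flags);
2. estimates each spot's **intrinsic fold variability** by non-parametric
   bootstrap — two pseudo-groups resampled with replacement from the
   control replicates, 95% quantile of the orientation-free fold between
   their means — and smooths those quantiles with a Gaussian GLM on log
   mean volume and gel position into **spot-specific thresholds**;
3. calls **differential expression** by a dual criterion: Welch t-test with
   Benjamini–Hochberg FDR control *and* fold change exceeding the spot's
   predicted threshold, with optional re-validation against an independent
   reference line (direction concordance + one-tailed Welch p);
4. answers the pilot **power / sample-size** question (fraction of spots
   reaching a target power per replicate count and fold, classical
   noncentral-t or exact Welch power);
5. **deconvolves mixed spots** from MS hit lists: score-based confidence
   filtering, NSAF (length-normalized spectral abundance) per protein per
   condition, and triage of each protein as concordant with the gel
   regulation, discordant, or unresolvable without a Western blot;
6. ships a **synthetic-data generator** (log-normal volumes with an
   abundance- and position-dependent CV structure, spike-ins, multinomial
   spectral counts) so the entire pipeline is testable without gel data.

## CLI

All stages are subcommands of `2dedd`:

```sh
2dedd simulate   --config sim.yaml --out data/ --seed 1
2dedd normalize  --spots data/spots.csv --out normed.csv --report report.csv
2dedd variability --spots normed.csv --n-boot 1000 --quantile 0.95 \
                  --subgroups 7,7 --seed 2 --out profile.csv
2dedd detest     --spots normed.csv --profile profile.csv --alpha 0.05 \
                 --scale log --reference wildtype --out de_results.csv
2dedd power      --spots normed.csv --power 0.8 --folds 2,1.5 --n 2:12 \
                 --coverage 0.96 --out power.csv
2dedd deconvolve --hits-control hits_c.tsv --hits-knockdown hits_k.tsv \
                 --de de_results.csv --min-ratio 1.5 --out triage.csv \
                 --worklist wb_worklist.csv
2dedd run        --config run.yaml --out results/ --seed 1
```

`2dedd run` executes every stage from one YAML/JSON config; a single seed
fans out deterministically to all stages, outputs carry a config hash +
seed header, and `provenance.json` records everything needed to reproduce
the run. Example config:

```yaml
simulate:
  n_spots: 2000
  n_replicates_per_group: 7
  groups: [control, knockdown, wildtype]
  spiked_spots: [[0, 2.0], [1, 2.0, down]]
bootstrap: {n_boot: 1000, subgroup_sizes: [7, 7], quantile: 0.95}
alpha: 0.05
scale: log
out_dir: results
```

(Replace the `simulate:` section with `spot_table: path.csv` to analyze an
existing table; gel columns must be named `<group>_<replicate>`.)

## Library use

```python
from twodedd import (SimulationConfig, generate_spot_table,
                     normalize_total_volume, BootstrapSettings,
                     compute_variability_profile, select_differential)

cfg = SimulationConfig(n_spots=2000, spiked_spots=((5, 2.0),), seed=1)
table, truth = generate_spot_table(cfg)
table, report = normalize_total_volume(table)
profile = compute_variability_profile(table, BootstrapSettings(seed=2))
de = select_differential(table, profile, alpha=0.05)
print(de.summary())
```
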