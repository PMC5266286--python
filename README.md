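# nichepart

Trophic-niche partitioning analysis for a three-species lake fish
community (Arctic charr, European whitefish, brown trout), built around
gill-net survey tables, stomach-content compositions and stable-isotope
samples:

- **catch metrics** — CPUE (fish per 100 m² net area per night),
  habitat-use proportions, size and biomass summaries
  (`nichepart.catch`);
- **diet composition** — pooled-sum volumetric prey abundance over six
  fixed prey categories, empty-stomach proportions, per-cell profiles
  (`nichepart.diet`);
- **overlap metrics** — Schoener's proportional-similarity index for
  diet and habitat profiles, pairwise matrices with a 0.60 significance
  threshold, between-year merge check (`nichepart.overlap`);
- **community PERMANOVA** — Bray–Curtis dissimilarities and a
  sequential-SS permutational MANOVA with residual (Freedman–Lane)
  permutation, exact enumeration on tiny designs
  (`nichepart.permanova`);
- **isotope mixing** — Bayesian linear mixing model with trophic
  enrichment correction (defaults Δ¹⁵N = 3.23 ± 0.79 ‰, Δ¹³C = 1.03 ±
  0.29 ‰), source uncertainty and concentration dependence, sampled by
  adaptive random-walk Metropolis on softmax coordinates
  (`nichepart.mixing`);
- **isotopic niche geometry** — standard ellipse area (SEA), its
  small-sample correction SEAc, convex-hull total area (TA), and
  intersection-over-union ellipse overlap (`nichepart.niche`);
- **synthetic data** — a seeded generator producing catch, stomach and
  isotope tables from the exact statistical structure the analysis
  assumes, with recorded ground truth (`nichepart.simulate`).

## Command line

```sh
nichepart simulate --out out/ --seed 42          # synthetic survey + full pipeline
nichepart cpue      --config config.yaml --out out/
nichepart diet      --config config.yaml --out out/
nichepart overlap   --config config.yaml --out out/
nichepart permanova --config config.yaml --out out/ [--seed N]
nichepart mix       --config config.yaml --out out/ [--seed N]
nichepart niche     --config config.yaml --out out/
```

`config.yaml` names the input tables and settings, e.g.

```yaml
inputs:
  fish: data/fish.tsv        # one row per fish; taxon columns mapped to
  effort: data/effort.tsv    # the six prey categories via prey_taxon_map
  isotopes: data/isotopes.tsv
seed: 42
overlap_threshold: 0.60
mcmc: {chains: 4, iterations: 4000, burn_in: 1500}
permutations: {count: 999}
```

All tables are UTF-8 comma- or tab-delimited text with a header row.
Validation is total: every malformed row is reported with its row
number, and nothing is silently dropped. Exit code is non-zero on any
validation failure; `--log-level INFO` enables structured logging on
stderr.

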