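# spikequant

Spike-in based absolute quantification of 16S rRNA amplicon communities,
with the dual **relative vs quantitative** community analyses that the
approach enables.

Amplicon sequencing alone yields relative abundances. Adding synthetic
spike-in standards at known copy numbers before PCR lets each sample carry
its own calibration: a per-sample log–log standard curve maps read counts
back to template copies, which — scaled by the DNA recovery ratio `R` and
filtered water volume `V` — become **16S gene copies per liter**:

```
y = a·x + b            # OLS fit: y = log10(spike-in reads), x = log10(added copies)
Y_otu  = 10^((log10(reads) − b) / a)
AB_otu = Y_otu / (R · V)          # copies per liter
```

The package then runs both branches side by side:

- **quantify** — table cleaning (spike-in / archaea / chloroplast /
  singleton removal), per-sample standard curves, copies-per-liter
  estimation, rarefaction, relative abundances
- **diversity** — richness, Chao 1 (bias-corrected), Shannon, Faith's PD,
  rarefaction curves
- **compare** — Bray–Curtis, PCoA, symmetric Procrustes with a Monte-Carlo
  test (M², permutation p), per-OTU Spearman concordance (BH-FDR),
  taxonomy-level aggregation
- **network** — signed Spearman co-occurrence networks (|r| ≥ 0.6,
  BH-adjusted p < 0.05 on OTUs above 0.1% overall abundance) and their
  attribute block (average degree, clustering, path length, Louvain
  modularity, components)
- **drivers** — Mantel tests (per-variable, environmental and geographic
  distances), RDA-based variation partitioning with Ezekiel-adjusted R²,
  sparse PLS subgroup–variable selection, variable correlation matrix
- **simulate** — a synthetic experiment generator with known ground truth:
  lognormal communities on a transect crossing the antimeridian,
  distance-decay spatial structure, nine spike-ins at 10³/10⁴/10⁵/10⁶
  copies (3/2/2/2), multinomial sequencing, per-OTU efficiency noise

## Command line

Every stage is a subcommand; all write TSV/JSON/GraphML outputs with a
version + seed comment header under `--out-dir`.

```bash
# end-to-end on a simulated experiment
spikequant all --out-dir out --seed 1

# or stage by stage on your own files
spikequant simulate --out-dir sim --seed 1 --n-samples 20 --n-otus 1200
spikequant quantify  --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
                     --design sim/design.tsv --meta sim/metadata.tsv \
                     --out-dir out --seed 1
spikequant diversity --counts ... --tree sim/tree.nwk --out-dir out
spikequant compare   --counts ... --out-dir out
spikequant network   --counts ... --out-dir out
spikequant drivers   --counts ... --out-dir out
```

Input formats: TSV count table (rows = OTUs, columns = samples; pass
`--transpose` for the other orientation), TSV taxonomy (`lineage`,
`category`), TSV spike-in design (`added_copies`), TSV sample metadata
(environment, longitude/latitude, `recovery_ratio`, `volume`), newick tree
with branch lengths. A YAML `--config` file can override any `RunConfig`
field (rarefaction depth, correlation cutoffs, permutation count, seed,
Shannon base, …) and carries an optional `sim:` section for `all`.

## Notes on conventions

- The quantitative branch uses the unrarefied cleaned counts; the relative
  branch uses the table rarefied to the minimum sample depth (configurable).
- Spike-ins with zero reads are excluded from the curve fit (no
  pseudocounts); a sample needs ≥ 3 positive spike-ins to calibrate.
- A "singleton" is an OTU with total count 1 across the whole table.
- Longitude is normalized to [−180°, 180°]; geographic distances are
  haversine km and handle antimeridian crossing.
- Network modularity is Newman Q of a seeded Louvain partition on the
  unweighted, sign-ignored graph; path length averages over connected
  pairs only.
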