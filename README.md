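# atlasdecon

Marker-based whole-body transcriptome deconvolution and categorical
expression accounting for insect tissue atlases.

## The problem

Bulk RNA-seq atlases of dissected body parts (for a mosquito: head, thorax,
abdomen, gut, Malpighian tubules, ovaries) describe each part's
transcriptome in TPM — a *relative* scale on which every sample sums to
10⁶. Relative profiles alone cannot answer quantitative questions such as
*what fraction of the whole animal's transcripts come from the ovaries?* or
*which gut region actually produces most peptidase transcripts?*
`atlasdecon` implements the analyses that recover those absolute answers
from relative data:

* **Whole-body deconvolution.** Writing `X_c(g)` for the mean TPM of gene
  `g` in body part `c` and `w_c` for the fraction of whole-body transcripts
  contributed by that part,

  ```
  Σ_c X_c(g) · w_c ≈ X_wb(g)        with  Σ_c w_c = 1
  ```

  when the dissected parts tile the body. For a **marker gene** of part `c`
  (≥ 5 TPM there and ≥ 50-fold above every other part) the other terms
  vanish, so each marker yields a direct estimate `ŵ_g = X_wb(g) / X_c(g)`;
  a part's scaling factor is the mean over its markers. The estimate is
  validated by predicting the whole-body profile from the parts and
  regressing log prediction on log observation, shedding gross outliers by
  studentized residual.
* **Investment / yield / output accounting.** A compartment's *investment*
  in a curated gene category is the summed TPM of the category's genes —
  the fraction of its own transcriptome spent on that function. Weighting
  investments by the RNA *yield* per dissected organ (ng/organ =
  concentration × volume / organs pooled) converts them into *outputs*:
  each compartment's absolute share of the category's transcripts.
  Percent-of-max scaling, top-N gene censuses and a one-sided
  hypergeometric over-representation test complete the toolkit.
* **Blood-meal wave clustering.** Over a 0/6/24/48 h post-blood-meal
  course, genes below 2 TPM are censored, profiles are z-scored
  (`z = (x − µ)/s`), hierarchically clustered, and each cluster labeled
  rapid / intermediate / delayed × induced / repressed from the timing and
  sign of its centroid's extremal deviation from baseline.
* **Cross-species signature censorship.** Matched compartments of two
  species are compared over one-to-one orthologs (subset, rescale to TPM,
  regress in log10(x+1) space). The most disparate significantly
  differential pair is censored, the survivors rescaled, and the fit
  recorded, step by step — isolating the small "species signature" of
  highly, disparately expressed genes that masks an otherwise strong
  correlation.

A ground-truthed synthetic generator (`atlasdecon.simulate`) produces
atlases with known mixing weights and planted markers, wave-template time
courses, paired species profiles with planted signature pairs, and
two-group designs with planted fold-changes, so every stage is tested
against recoverable truth without any data download.

## Worked example

Recover mixing weights from a simulated noisy atlas (20,000 genes, six
compartments, 12 planted markers each, log-normal replicate noise):

```python
import atlasdecon as ad

matrix, sheet, truth = ad.generate_atlas(noise_sd_log=0.2, n_replicates=3, seed=42)
grouped = ad.aggregate_replicates(matrix, sheet, ("compartment",))
profiles = {key[0]: prof for key, prof in grouped.items()}
whole_body = profiles.pop("whole_body")

census = ad.find_markers(profiles, min_tpm=5, min_fold=50)
factors = ad.estimate_scaling_factors(census, profiles, whole_body)
total, warn = ad.sum_check(factors)

print(factors.to_frame().round(4))
print(f"sum of scaling factors: {total:.1f}%")

report = ad.validate_prediction(ad.predict_whole_body(profiles, factors), whole_body)
print(f"slope {report.slope:.3f}, R^2 {report.r_squared:.3f}, "
      f"outliers removed {len(report.removed_outliers)}")
```

prints

```
                    fraction  percent  n_markers      sd
compartment
abdomen               0.1497  14.9739         12  0.0335
gut                   0.1238  12.3753         12  0.0172
head                  0.1614  16.1407         12  0.0164
malpighian_tubules    0.2464  24.6381         12  0.0406
ovaries               0.1438  14.3845         12  0.0287
thorax                0.2253  22.5343         12  0.0479
sum of scaling factors: 105.0%
slope 1.002, R^2 0.994, outliers removed 1
```

Each `fraction` is that part's estimated share of the whole-body
transcriptome (the planted weights here were head 0.158, thorax 0.214,
abdomen 0.139, gut 0.124, Malpighian tubules 0.233, ovaries 0.132 — every
estimate lands within ~0.02 of truth at this noise level). The `sd` column
is the spread of the per-marker estimates; the total is reported as-is,
not forced to 100%. The validation regression's slope ≈ 1 and high R²
confirm the factors predict the observed whole-body profile.

The same workflows are scriptable from the shell:

```sh
atlas-decon simulate --mode atlas --seed 1 --out-dir sim/
atlas-decon deconv --matrix sim/matrix.tsv --samples sim/samples.tsv --out-dir results/
atlas-decon waves --matrix tc/matrix.tsv --samples tc/samples.tsv --k 6 --out-dir results/
```

See `atlas-decon --help` for the `markers`, `invest`, `enrich`, `de` and
`xspecies` subcommands; every flag can also be set in a flat YAML file
passed with `--config` (explicit flags win).

## Layout

| module | contents |
| --- | --- |
| `atlasdecon.containers` | validated expression/metadata containers |
| `atlasdecon.io`, `.config` | TSV/JSON/YAML interchange, deterministic reports |
| `atlasdecon.core` | TPM conversion, replicate aggregation, Welch+BH gate |
| `atlasdecon.markers` | exclusive-marker census, reference-relative enrichment |
| `atlasdecon.deconv` | scaling factors, whole-body prediction, validation fit |
| `atlasdecon.investment` | investment / yield / output, top-N, over-representation |
| `atlasdecon.waves` | z-scoring, hierarchical clustering, wave labels |
| `atlasdecon.xspecies` | ortholog correlation, sequential censorship |
| `atlasdecon.simulate` | ground-truthed synthetic data generators |

Design notes and modelling assumptions are documented in
[`docs/methods.md`](docs/methods.md).
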