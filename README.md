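# decompscore

Sensory-driven decomposition scoring for seafood LC-HRMS metabolomics.

Regulatory seafood testing judges spoilage ("decomposition") by expert
sensory analysis on a 1–100 scale: scores below 50 pass, scores above 50
fail. `decompscore` implements a chemical alternative: it models the
expert's score from an untargeted LC-HRMS peak-area table, so that a
mass-spectrometry measurement yields a *sensory-like* decomposition
score and a pass/fail call directly comparable to the sensory result.
It is aimed at food-safety and metabolomics scientists who have an
aligned feature table (compounds × samples, with neutral monoisotopic
mass and retention time per compound) and per-sample sensory scores.

## Method

Per product, the pipeline is:

1. **Segregation.** Samples split into decomposed (score > 50) and
   nondecomposed (score < 50) groups; a score of exactly 50 is rejected
   as undefined.
2. **Volcano differential selection.** For each compound *i*,
   log₂FC*ᵢ* = log₂[(mean area in decomposed + ε)/(mean area in
   nondecomposed + ε)] and a two-sided Welch *t*-test p-value *pᵢ* on
   log₂(area + ε). The 100 compounds with the lowest *pᵢ* among those
   with |log₂FC*ᵢ*| > 1 become the compounds of interest (ε = 1 area
   unit keeps gap-filled zeros finite).
3. **Two-stage Random Forest regression.** One third of the samples
   (nearest-integer rounding, seeded) are held out as the test set. A
   2000-tree regression forest is fit to the training scores on the 100
   compounds, compounds are ranked by permutation importance, and the
   panel size *k* is optimized: for each *k*, a forest on the top-*k*
   compounds is scored by the Pearson correlation *r* between training
   scores and out-of-bag predictions; the smallest *k* maximizing *r*
   defines the final panel and model.
4. **Evaluation.** Test-set predictions give the per-product
   correlation *r*(sensory, modeled) and qualitative calls at the
   50-point boundary: a false positive is sensory < 50 with modeled
   \> 50, a false negative the reverse. Reproducibility is the range
   (max − min) of the three modeled scores for portions extracted on
   three separate days (one each from the low, borderline, and high
   decomposition states), summarized as the fraction of ranges within
   5/10/15 points.
5. **Annotation.** Panel compounds are matched to a packaged reference
   library of 112 decomposition markers (biogenic-amine derivatives,
   DNA degradation products, lipids, unknowns) by inclusive tolerance
   windows: ±5 ppm neutral mass, ±0.2 min retention time.

A synthetic-data generator reproduces the study design — per product, 7
quality increments × 5 sample portions × duplicate extraction days plus
three third-day replicates (73 samples; 83 for an 8-increment product)
— with planted monotone marker compounds, multiplicative lognormal
noise, and day batch effects, so the whole pipeline is testable without
instrument data.

## Worked example

Simulate two products at the default study design and run the full
pipeline (console output below is what the command prints):

```sh
$ decompscore run --products CHUM,SQD --seed 13 --trees 200 --out demo
{
 "correlations": {
  "CHUM": 0.9989877773854176,
  "SQD": 0.9989283661939454
 },
 "fn_total": 0,
 "fp_total": 0,
 "n_test_total": 48,
 "n_triplicates": 6,
 "products": ["CHUM", "SQD"],
 "range_proportions": {"5.0": 100.0, "10.0": 100.0, "15.0": 100.0}
}
```

Each simulated product has 73 samples, of which 24 (one third, nearest
rounding) form the test set. The modeled scores track the sensory
scores with r ≈ 0.999 per product, no sample crosses the 50-point
boundary in the wrong direction (0 false positives/negatives in 48 test
samples), and all six triplicate ranges fall within 5 points —
qualitatively the behavior expected of the method on real products.
`demo/` then contains `product_summary.csv` (per-product n, test-set
size, correlation, FP/FN counts), `predictions.csv` (sensory vs modeled
score per test sample), `triplicate_ranges.csv`, per-product model
bundles and annotation reports, and `manifest.json` recording every
seed and option so the run can be reproduced bit-for-bit.

The same stages are available on your own data:

```sh
decompscore fit --features features.csv --sensory sensory.csv --seed 7 --out model.json
decompscore predict --model model.json --features features.csv --out predictions.csv
decompscore evaluate --predictions predictions.csv --sensory sensory.csv --out eval/
decompscore annotate --features features.csv --out annotation.csv
```

or from Python via `decompscore.fit_product_model`,
`decompscore.predict_scores`, `decompscore.evaluate_product`, etc.

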