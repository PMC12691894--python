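# healthfin

Typology analysis of national health-financing systems. Starting from a
22-year country panel of twelve indicators — out-of-pocket, voluntary and
compulsory health spending (each per capita and as % of GDP), plus
healthy-life-expectancy (HALE) and infant-mortality outcomes by sex — the
pipeline:

1. **Time-weights** each country's series with exponential weights
   `w_t ∝ exp(λ·(t − t₀)/(T − t₀))`, λ = 1.5, so the final year counts
   about 4.5× the first;
2. **Reduces** each spending group's (per-capita, %GDP) pair to its first
   principal component on standardized columns, giving a country × 3
   score matrix;
3. **Embeds** the scores with classical (Torgerson) metric MDS into three
   dimensions, reporting Kruskal stress-1 and the Shepard correlation;
4. **Clusters** the coordinates with K-means (k = 4, 50 random starts,
   deterministic relabeling) into financing typologies, validated by the
   mean silhouette width, the between/total sum-of-squares ratio and a
   multi-seed stability check;
5. **Scores performance** with TOPSIS over (HALE, infant mortality) —
   closeness `100·d⁻/(d⁺+d⁻)` to the ideal point — plus a 3-tier outcome
   clustering and per-cluster success rates at threshold 70;
6. **Tests sex gaps** (female − male HALE, male − female infant
   mortality) across typologies with one-way ANOVA and Tukey–Kramer
   comparisons (which tolerate singleton clusters).

A synthetic-data generator (`healthfin.simulate`) plants known typologies,
outcome links and gap structure so every stage can be checked against
ground truth. The package also ships the published 3-D coordinates of 38
OECD health systems (`healthfin.load_reference_coordinates()`), used by
the tests and the acceptance script.

## Worked example

```python
import healthfin as hf

truth = hf.truth_defaults()                      # 38 countries, 4 typologies
panel = hf.simulate_panel(truth, n_years=22, seed=7)

res = hf.financing_pipeline(panel)               # weight → PCA → MDS → K-means
res.solution.sizes()                             # array([17, 12,  8,  1])
round(res.solution.silhouette, 3)                # 0.591
round(res.embedding.stress1, 12)                 # 0.0 (3-D scores embed exactly)

from sklearn.metrics import adjusted_rand_score
adjusted_rand_score(truth.planted_label,
                    res.labels.reindex(truth.planted_label.index))  # 0.922

scores = hf.topsis_scores(
    hf.normalize_outcomes(res.weighted[["hale_total", "im_total"]]))
hf.success_rates(scores, res.labels)             # per-cluster success table

gaps = hf.compute_gaps(res.weighted, res.labels)
hf.oneway_anova(gaps["hale_gap"], gaps["cluster"]).f_stat  # 23.79
```

The numbered scripts under `analysis/` run the same stages as a pipeline
over CSV files in `results/`:

```sh
python analysis/01_simulate_panel.py --seed 7
python analysis/02_weight_reduce_embed.py
python analysis/03_cluster_typologies.py
python analysis/04_performance_topsis.py
python analysis/05_gender_gaps.py
python analysis/06_lambda_sensitivity.py
```

## Layout

- `src/healthfin/` — library: `panel` (I/O, validation, config),
  `weighting`, `grouppca`, `mds`, `cluster`, `topsis`, `gaps`,
  `simulate`, `pipeline`.
- `src/healthfin/data/` — packaged OECD coordinate table.
- `analysis/` — numbered driver scripts.
- `scripts/acceptance.py` — standalone metric report.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — methods, parameter defaults and known limitations.
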