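# regalforage

Sex-specific floral-visitation analysis for protandrous pollinators.

In many butterflies and bees, males emerge weeks before females.  Because
flowering communities turn over within a season, the two sexes of one
species can encounter — and feed on — substantially different plant
assemblages, with consequences for nutrition, pollination networks and
conservation planning.  `regalforage` implements a complete, tested
pipeline for long-term visitation surveys of such species (its defaults
emulate a 21-year Pollard-walk survey of the eastern regal fritillary),
answering three questions:

1. **Do the sexes visit different plants?**  Per-year richness and
   effective species number (`exp` of Shannon entropy, the Hill number of
   order 1) compared with the paired mixed model
   `metric ~ sex + (1 | year)`; per-year Morisita–Horn dissimilarity

   `d_mh(x, y) = 1 − 2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²) · X · Y]`

   tested against 1000 Patefield random tables (fixed row/column margins,
   the permutation null of re-paired visit labels) with percentile 95%
   intervals; and a pooled sex × plant chi-squared test whose Pearson
   residuals label each plant female- or male-associated.
2. **How much is phenology?**  Each year is restricted to its overlap
   window — the first week in which females reach 25% of observations
   through the last week at or below 75% — and the analyses repeat on that
   dataset; a post-hoc regression relates yearly d_mh to the female–male
   median-date gap.
3. **Does nectar chemistry track the split?**  Concentrations of focal
   sugars and amino acids are screened for 4·SD outliers and compared
   between female- and male-associated species with heterogeneous-variance
   planned contrasts (species-specific variances, Welch–Satterthwaite df)
   under Bonferroni-corrected alphas.

A synthetic-data generator with known ground truth (protandrous flight
curves, seasonal bloom turnover, sex-specific preferences, ambiguous
congeneric labels, heteroscedastic nectar panels) makes every stage
verifiable without any external download.  See `docs/methods.md` for the
full model descriptions.

## Worked example

```python
from regalforage import (SeasonConfig, simulate_season, yearly_null_tests,
                         diversity_table, paired_sex_comparison)

dataset, truth = simulate_season(SeasonConfig(), seed=1)   # 21 years
results = yearly_null_tests(dataset, n_reps=1000, seed=1)
esn = paired_sex_comparison(diversity_table(dataset),
                            "effective_species_number")
```

Running `python examples/05_dissimilarity_null.py` prints the per-year
table, ending with:

```
2017   0.206  [ 0.002,  0.056]  above
2018   0.437  [ 0.005,  0.072]  above

mean d_mh = 0.369; 21/21 years more dissimilar than the null.
```

Every year's observed dissimilarity (here 0.206–0.506, mean 0.369) sits
above the null interval: the sexes' plant use differs far more than random
re-pairing of visits with plants would produce.
`examples/04_diversity_mixed_model.py` prints the diversity contrast:

```
effective_species_number: female - male = +1.761 (SE 0.125, t = 14.10,
p = 4e-45, mixed_reml, 21 paired years)
```

— under these synthetic conditions females visit about 1.8 more
effective species than males.  The remaining examples
(`examples/0*.py`, one per capability) cover ambiguous-thistle assignment,
overlap windows, the pooled chi-squared labeling, nectar contrasts and the
end-to-end pipeline; each prints what it computes and what the numbers
mean.  The same stages are scriptable from the shell:

```sh
regalforage simulate --seed 1 --years 21 --out visits.csv
regalforage run-all --visits-csv visits.csv --out reports --seed 1
```

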