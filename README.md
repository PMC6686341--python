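# firerefugia

Do unburned islands inside wildfire perimeters act as fire refugia for
greater sage-grouse (*Centrocercus urophasianus*)? This package implements
the full analysis pipeline for that question, aimed at fire ecologists and
wildlife biologists working with lek-count monitoring data and mapped fire
histories:

1. **Fire-context classification** — each lek (communal mating site, whose
   yearly peak male count indexes the local population) is assigned to one
   of four categories: *unburned island* (inside an island, or < 50 m from
   an island or perimeter edge), *fire perimeter* (inside the burn),
   *small buffer* (50 m–1.5 km outside), or *large buffer* (1.5–6.4 km
   outside, the control); leks farther than 6.4 km are excluded.
2. **Before/after trend model** — for each lek passing four inclusion
   filters (in a category; surveyed ≥ 6 years; ≥ 2 counts before and after
   its fire; not already extirpated pre-fire), a Poisson GLM with log link

   E(ln Y) = β₀ + β₁X₁ + β₂X₂ + β₃X₁X₂

   is fitted by iteratively reweighted least squares, where Y is the male
   count, X₁ the survey year and X₂ the after-fire indicator. The prefire
   attendance trend is β₁ and the postfire trend β₁ + β₃ (log males/year).
3. **Category comparison** — pre- vs postfire slope distributions per
   category, with a Shapiro–Wilk normality gate choosing between a Welch
   two-sample t test and a Wilcoxon rank-sum test.
4. **Postfire habitat composition** — burning is simulated from the fire
   record (everything burned within 17 years before a lek's fire year
   counts as burned, since sagebrush needs 35–120 years to recover);
   vegetation height of burned/unsuitable cells is set to 0 m, and
   cheatgrass suitability follows an elevation-thresholded rule (burned
   below 2,000 m ⇒ > 8 % cover assumed). Mean sagebrush height, unsuitable
   cheatgrass fraction and mean elevation are extracted in discs of 0.8,
   6.4 and 18 km around each lek.
5. **Multimodel inference** — postfire slopes are regressed on the nine
   standardized covariates with OLS over the constrained candidate set
   (each variable absent or at exactly one scale: 4³ − 1 = 63 models),
   ranked by AICc, and coefficients averaged with Akaike weights
   (full-set averaging by default; conditional available). Spearman/VIF
   collinearity screening (|r| < 0.5, VIF ≤ 3) is provided.

A synthetic-landscape generator (blob-shaped fires with tunable unburned
island fractions, height-class-coded sagebrush vegetation, elevation and
cheatgrass fields, Poisson count series with known true trends) makes the
whole pipeline testable without any data downloads.

## Worked example

Run the bundled small fixture (a 15 × 15 km landscape, 6 fires, 12 leks):

```
firerefugia run-all --config configs/fixture_small.yaml --out-dir results/demo
```

The manifest reports 12 leks classified, 12 passing the inclusion filters,
four categories compared and 63 candidate models fitted. The category
comparison table (`category_comparisons.csv`) from this run:

```
category,n_leks,test,statistic,df,p_value,...
fire_perimeter,3,welch_t,5.98,3.98,0.0040,...
large_buffer,3,welch_t,-0.01,2.61,0.9930,...
small_buffer,3,welch_t,3.22,3.96,0.0327,...
unburned_island,3,welch_t,-5.51,3.80,0.0061,...
```

Read: burned leks' postfire trends dropped significantly below their
prefire trends (t = 5.98 with mean trend falling from +0.07 to −0.17 log
males/year), the far-away control leks were unaffected (t ≈ 0, p = 0.99),
and the unburned-island leks in this replicate actually trended *up* after
fire — the planted ground truth for that category is a stable trend, so
sampling noise at n = 3 can tip either way. `trend_fits.csv` holds the
per-lek coefficients and slopes, and `averaged_coefficients.csv` the nine
AICc-averaged habitat effects with 95 % confidence intervals.

Real data go in through the same stage commands (`classify`, `trends`,
`compare`, `habitat`, `infer`) using CSV counts, GeoJSON perimeters with a
`fire_year` property, and ESRI ASCII grids in one planar metric CRS.

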