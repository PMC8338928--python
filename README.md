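# hydromove

Movement ecology of wetland birds against changing surface water.

`hydromove` links hourly GPS telemetry of wetland specialists (its study
system is Shoebill-like waders living in seasonally flooded tropical
wetlands) to changes in surface water, measured from satellite reflectance
as the Normalized Difference Water Index

```
NDWI = (Green − NIR) / (Green + NIR)
```

(+1 ≈ open water, −1 ≈ dry land), consumed as 8-day, 500 m composites.
It is written for movement ecologists who want a tested, reproducible
version of this analysis chain:

1. **Tracking IO** — read hourly fixes (06:00–18:00 local, UTC+02:00),
   filter speed outliers (> 150 km/h between consecutive fixes, greedy
   against the last retained fix), classify bird-days into juvenile /
   immature / adult age windows with 1 May season boundaries.
2. **Daily movement metrics** — maximum pairwise great-circle distance per
   day (haversine, R = 6371.0088 km), with overnight displacement allocated
   to the previous day; the **Moving-Day threshold** is the smallest whole
   kilometre below which ≥ 80% of daily movements fall.
3. **Residence-area segmentation** — runs of ≥ 2 consecutive non-moving
   days become candidate Areas; consecutive candidates whose 95% minimum
   convex polygons (5% of points farthest from the centroid peeled)
   intersect are merged, cascading until stable.
4. **Kernel home ranges** — bivariate-normal KDE on a 500 m grid with the
   reference bandwidth `h_ref = 0.5 (sd_x + sd_y) n^(−1/6)`; 95% and 50%
   isopleth areas per bird and May→April season-year.
5. **Surface-water sampling** — daily mean NDWI at bird positions
   (nearest cell), per analysis phase: presence, last week before
   abandonment, first week after arrival, and the occupied locations
   re-evaluated over the week after abandonment. Composites need ≥ 92%
   good pixels and ≤ 2% unclassified.
6. **Paired binomial mixed models** —
   * model (a): presence (0) vs post-abandonment (1), NDWI as a degree-2
     orthogonal polynomial (`poly 1`, `poly 2`);
   * model (b): last week before abandonment (0) vs first week after
     arrival at the next area (1), NDWI linear;
   both with random intercepts for year and for Area nested within bird,
   fitted by Laplace-approximated maximum likelihood, reported with Wald z
   tests and Nakagawa marginal/conditional R²
   (`R²_m = σ²_f / (σ²_f + Σσ²_r + π²/3)` on the logit scale).
7. **Synthetic data** — a seeded generator of stay/move trajectories and
   NDWI composite series with known residence areas, moving days and
   drying/wetting trends (δ) so that every stage, and both models, can be
   tested without any satellite download or tracking archive.

## Worked example

```python
import hydromove as hm
from hydromove.pipeline import analyze_bundle

bundle = hm.end_to_end_fixture("adults", seed=1)   # drying preset, δ = −0.05
res = analyze_bundle(bundle)
```

prints, via the snippet in `docs/methods.md`:

```
Moving-Day threshold: 2 km (covers 93% of 1656 bird-days)
Residence areas (Oct-Dec, all birds/years): 131
mean daily NDWI: presence -0.504 -> week after abandonment -0.535
       term  estimate    se       z     p
(Intercept)    -0.774 0.654  -1.183 0.237
 ndwi_poly1  -179.378 7.502 -23.911 0.000
 ndwi_poly2    -4.282 6.900  -0.621 0.535
marginal R2 = 0.540, conditional R2 = 0.865
```

Reading this: the six simulated birds' daily movements put the Moving-Day
threshold at 2 km; 131 residence areas are segmented in the Oct–Dec
windows; the same locations are drier the week after abandonment (−0.535
vs −0.504), and model (a) detects that as a strongly negative first-degree
NDWI term — abandonment probability rises toward drier values, the drying
signature. The wetting preset (`"immatures"`, δ = +0.10) flips that sign,
and under the `"null"` preset the selection model (b) shows a
non-significant NDWI term with marginal R² < 0.001.

A command-line interface mirrors the stages
(`hydromove simulate|clean|metrics|run-all ...`); `run-all` writes every
stage output plus a `manifest.json` whose hashes are byte-identical across
reruns of the same configuration.

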