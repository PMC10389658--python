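# Methods

This note documents the models, conventions and numerical choices behind
`lingscape`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the known limitations.

## Sampling-region geometry

Each language is located by a single WGS84 point. Its environmental
catchment is built as follows.

1. **Equal-area buffer.** The point is projected into a spherical
   world-sinusoidal projection (`x = R·λ·cos φ, y = R·φ`,
   R = 6371.0088 km), buffered by 100 km as a 128-segment polygon, and
   transformed back to lon/lat. Because the projection is exactly
   equal-area on the sphere, the buffer covers ~π·100² km² at any
   latitude; the 128-gon approximation plus edge re-densification keeps
   the deviation under 0.05% (the tolerance budget assumes this segment
   count). Points whose buffer would cross a pole are rejected; points
   within 2° of the antimeridian are warned about — the bounding box is
   [−180, 180] × [−90, 90] with no wraparound.
2. **Coastline clip.** The buffer is intersected with the land
   multipolygon; an empty result (off-shore point) is kept as an empty
   region with a warning so the language survives into the master table
   with missing environmental cells.
3. **Voronoi partition.** A planar Voronoi diagram is computed on raw
   lon/lat *degrees*, not on great-circle or projected distance. This is
   deliberate: it mirrors the rectangular-box Voronoi of the original GIS
   workflow, including its high-latitude distortion. Coincident points
   (< 1e-6°) are rejected rather than jittered.
4. **Constraint.** Each Voronoi cell is intersected with the union of
   *all* clipped buffers. Using the combined union rather than the
   language's own buffer reproduces a known artifact: a region can annex
   buffer area of a neighbour. Note that when Voronoi adjacency and
   buffer construction share a metric this is impossible (a point nearer
   to language *i* than to *j* that lies within *j*'s 100 km disc must
   lie within *i*'s); inflation arises precisely from the disagreement
   between degree-space adjacency and km-space buffers, and therefore
   appears at higher latitudes and in asymmetric configurations. The
   `inflation_ratio` (region area over the language's own land-clipped
   buffer area — the denominator choice is an assumption) quantifies it
   per language.

All areas are measured in the sinusoidal plane after densifying polygon
edges at 0.05° so that long degree-space edges do not bias the planar
image.

## Environmental summarisation

**Stations.** Annual station summaries (tmin/tmax/tavg °C, prcp mm) are
filtered to an inclusive year window — default 1951–1980, a 30-year
climate-normal period predating the acceleration of warming; gridded
humidity uses 1960–1980 because that source begins in 1960. Within a
region, the mean per parameter pools *all* station-year values (grand
mean), and the reported n is the number of contributing annual values,
not stations. Pooling, rather than averaging per-station means, was
chosen so that n matches the quantity actually averaged.

**Numeric rasters.** A cell contributes iff its centre lies strictly
inside the region polygon (boundary ties resolved by the even-odd rule).
Reported statistics: n, null cells, min, max, range, mean, median, first
and third quartiles, standard deviation, variance, coefficient of
variation. Quartiles use linear interpolation between order statistics
(the "type 7" rule; configurable), variance is the sample (n−1) variance,
and the coefficient of variation is sd/mean, absent when the mean is 0.
Zero contributing cells yield absent statistics with n = 0.

**Categorical rasters.** Per-class cell counts over the same
cell-inclusion rule; classes absent from a region are reported as 0 and
codes missing from the class map are warned about and excluded, so
counts always sum to n − null_cells.

**Naming.** Every environmental variable is
`v_<short_name>_<units>__<stat>`; the double underscore unambiguously
separates the statistic (which may itself contain single underscores,
e.g. `std_dev`).

## Phonological indices

Derived indices are *never stored*: `LanguageRecord` keeps only the
primitive fields and recomputes `OnsCoda`, `ConsHeavy = OnsCoda +
CTotal/4`, `CHeavyObstr = OnsCoda + Obstr/3`, `CHeavyLog = OnsCoda +
ln(CTotal)`, `ObsPct`, `SegTot` and `CplusVQ` on access, so file and
memory can never disagree. Derived columns present in an input CSV are
advisory: they are checked against the recomputed values (mismatches
> 1e-6 logged) but never trusted. The logarithm base in `CHeavyLog` is
a documented assumption: the published range minimum (≈1.80) is
consistent with ln(6) = 1.79 and inconsistent with base 10 or 2, so the
natural log is used.

The tone ordinal maps None→0, Marginal→1, Simple→1, Moderately
Complex→2, Complex→3: marginal and simple systems are collapsed because
analyses group "non-tonal or simple-tone" languages as the low level;
only a complete absence of tone scores 0.

The vowel index is the proportion of vowel symbols among all classifiable
symbols in a transcribed wordlist, ignoring word boundaries and length
marks. Symbol classification is supplied explicitly per transcription
scheme; there is no orthography guessing, and unclassifiable symbols are
excluded with a warning when an explicit consonant set is given.

## Relatedness

Pairwise genealogical distance is an integer 1–10: 1 near-dialects, 2–8
increasingly distant relationship within an accepted family, 9 divided
expert opinion, 10 no accepted relationship (isolates score 10 against
everything). Distances are stored sparsely; a missing pair is read as 10
only when both languages are flagged as sharing no family, otherwise it
is an error — this prevents unscored pairs from being silently treated
as unrelated. Difference tables |x_i − x_j| exclude distance-10 pairs
(they carry no genealogical signal); distance-1 "dialect" pairs are
retained by default but filterable, since their status in trait analyses
is unsettled. Classes 3–7 are labelled "Level 3"…"Level 7" between the
named endpoints ("Dialect", "Close", "Distant", "Divided Opinions").

## Statistics

- Linear association: OLS; R² is the squared Pearson correlation and p
  the two-sided slope test. Constant x is an error; constant y returns
  slope 0, R² 0, p 1 by convention.
- χ² presence/absence: Pearson χ² on the 2×2 without Yates continuity
  correction by default (configurable); expected cell counts below 5 are
  flagged on the result. Continuous environments are dichotomised at the
  median (ties to the lower group) or at an explicit threshold.
- Two-group means: Welch's unequal-variance t-test (the comparison's
  source does not name its test; Welch avoids the equal-variance
  assumption at negligible cost).
- All operations use pairwise-complete deletion with the dropped count
  recorded, so every analysis carries its own effective n.
- Boxplot summaries share the type-7 quartile rule and use Tukey
  whiskers at 1.5·IQR.

## Synthetic world

The generator emulates the statistical structure the analysis assumes,
not real geography. All randomness derives from one root seed via
per-stage child seeds, so identical configurations give byte-identical
serialised worlds and each stage can be regenerated independently.

- **Land.** A unit-variance Gaussian random field (white noise smoothed
  with a Gaussian kernel of width `field_smoothness`, default 6°)
  thresholded at the (1 − land fraction) quantile; default land fraction
  0.35 over a 60° × 90° box. The coastline polygon is the exact union of
  land cells.
- **Languages.** Default 80 points on land, with latitude density
  ∝ exp(−2·|lat|/90) (languages denser in the tropics) and a 0.1°
  minimum separation.
- **Rasters** (default 0.5° cells). Elevation is a clipped smooth field
  (mean ≈ 600 m, sd 500 m, sea = 0). Temperature
  `tavg = 27 − 0.45·|lat| − 6.5·elev/1000 + noise(1 °C)`;
  tmax/tmin = tavg ± 6. Humidity, precipitation and biomass are
  increasing monotone transforms of tavg plus smooth noise, making them
  positively inter-correlated with temperature and negatively with
  elevation. Land cover: water over sea, snow where tavg < −5 °C, and
  biomass terciles (short/medium/tall vegetation) elsewhere.
- **Stations.** Density 40 per 10⁶ km² of land (≈1 station per ~3
  buffer areas, leaving a realistic fraction of languages without
  station coverage); per-cell intensity multiplied by
  max(0, 1 + north_bias·lat/90); one record per station-year over
  1951–1980 sampling the local raster value plus 0.5 °C observation
  noise (60 mm for precipitation).
- **Phonologies.** Latent heaviness `h = 12 − 0.15·T + ε`,
  ε ~ N(0, 1), clipped to [1.5, 33]. The onset+coda total is drawn from
  a broad integer marginal (≈N(2.5, 1.3) clipped to 0–6) *first* and
  CTotal — the finer 0.25-granularity term — absorbs the remainder,
  shifting the onset+coda total only if the rounded CTotal would leave
  [6, 128]. The rounding error is bounded by 0.25 and independent of T,
  so the planted slope is recoverable without bias. Optional planted
  links (switchable off for null tests): ejective probability rises
  logistically with elevation; tone complexity rises with the humidity
  percentile. Remaining fields are filled from fixed marginals; the
  vowel index is present for ~60% of languages.
- **Genealogy.** Languages are randomly partitioned into ~n/6 families;
  within a family each language takes a random path in a depth-3 binary
  tree and the pair distance is 1 + levels-to-join (capped at 8).
  Cross-family pairs are 10 except a 1% disputed fraction scored 9;
  singleton families are isolates.

What passing tests on this world do **not** show about real data: the
generator has no spatially clustered families (so relatedness and
geography are independent, unlike reality), no displacement history, no
realistic phoneme co-occurrence structure, stationary and isotropic
climate fields, and no station quality flags or missingness patterns.
Results on it validate the *machinery* — geometry, summarisation,
statistics, and recoverability of a known effect — not any substantive
claim about languages.

## Verification problem sizes

The acceptance script and test suite size their computations so a full
run completes in minutes on one core: the grid oracle for region
membership uses a 1000×1000 lattice over the buffer-union bounds with 25
languages; zonal statistics are checked against a brute-force per-cell
loop on 100 random 50×50 rasters; slope recovery uses n = 300 languages
× 200 replicates; χ² calibration uses n = 500 × 1,000 replicates. These
sizes give oracle agreements well inside the stated tolerances (≥99.5%
membership agreement, 0.5% area conservation, exact counts, 1e-9
moments) and standard errors small enough to detect a miscalibrated test
or biased estimator.

## Known limitations

- Voronoi adjacency in degree space is a fidelity choice, not a
  recommendation; a geodesic Voronoi would remove the high-latitude
  distortion *and* the inflation artifact.
- No wraparound at the antimeridian; circum-polar and date-line
  geographies are out of scope.
- Humidity is summarised as temporal mean grid first, then zonal
  statistics (the alternative order is available behind the extraction
  config); with smooth fields the two orders differ negligibly.
- No mixed-model or phylogenetic control for relatedness: the 1–10
  scale and difference tables are descriptive machinery; regression
  with genealogical covariance is future work.
- Real-data adapters are limited to the formats the generator emits
  (CSV, GeoJSON, ESRI ASCII grid); ingesting archival station or raster
  sources requires converting to these.
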