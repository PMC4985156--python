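# Methods

This note documents the models and procedures implemented in
`dualforage`, the defaults they ship with, the design choices made where
the procedure is usually subjective, and what the synthetic-data
experiments do and do not demonstrate.

## Geometry

All distances are great-circle distances on a sphere of mean radius
6371.0088 km. Simulation, path re-sampling and gridding run on a local
azimuthal-equidistant plane centred on the colony: a point at distance
d and initial bearing θ from the colony maps to (d sin θ, d cos θ) km.
Distances from the colony are exact on this plane; pairwise distances
carry a relative error of order (d/R)², i.e. below 10⁻⁴ across a
100-km study area, which is negligible against GPS error. Timestamps are
UTC; local clock time is UTC + a fixed offset (default +2 h, Central
European Summer Time) rather than a timezone database, for
reproducibility.

## Trip segmentation and metrics

A foraging trip is a maximal run of fixes farther than `buffer_km`
(default 0.5 km) from the colony, extended to the bounding
buffer-crossing fixes; runs spanning less than `min_trip_duration_h`
(default 0.5 h, the shortest trip the method should resolve) are
discarded. A trip bounded by crossings on both sides is *complete*.
Intervals are half-open, so a crossing fix shared by consecutive trips
creates no overlap in time.

Metrics: duration; foraging range R (maximum distance nest→fix); total
distance D (sum of successive great-circle legs); straightness
S = 2R/D, capped at 1 for complete trips (the cap absorbs the ≤ 2·buffer
shortfall of the first/last legs). Destination classes come from dwell
fixes — device speed below 10 km h⁻¹ outside the colony — classified by
the land/sea mask: `sea` when dwell is marine (open sea or tidal flat),
`inland` when over the mainland, `mixed` when each side holds at least
10% of the dwell fixes (the threshold is configurable; no standard rule
exists), `island` when the bird only dwelt on islands, and the class of
the most distant fix when there is no dwell at all.

Activity budgets report, per local hour or weekday, each individual's
share of trip fixes over land vs sea, then mean ± SE across individuals.
The sea/land variability contrast is tested with a two-sided variance-
ratio F-test (F = s²₁/s²₂ on n₁−1, n₂−1 df); mixed-model mean
comparisons are deliberately out of scope.

## First-passage time and ARS detection

FPT(r) at a path point is the time between the last entry into, and the
first exit from, a circle of radius r centred there; it is undefined
where the path starts or ends inside the circle (such points are
excluded, never zero-filled). Crossing times are found by linear
interpolation of the distance-to-centre function along path segments;
the implementation accelerates the search with a cumulative-maximum
trick and is verified exactly against a brute-force segment walk.

Before analysis, rest bouts (maximal runs of fixes below 3 km h⁻¹,
resting/preening on the water or ground) collapse to a single point
carrying the bout's first position and time, and the path is re-sampled
every 0.1 km along track so that evaluation points are equidistant in
space. Two nested passes are run per trip: r = 1–50 km step 1 km,
evaluated every 1 km (large-scale ARS), and r = 0.1–10 km step 0.1 km,
evaluated every 0.1 km (small-scale events). var(log FPT) per radius
(natural log; peak location is base-invariant) is computed over defined
values only and reported as undefined with fewer than three of them.

Candidate ARS scales are interior local maxima of the variance curve.
Peak picking runs on a 3-point moving average of the curve: this
automates what reading the variance plot by eye does — single-bin jitter
is not a scale — while raw variances are always reported. Up to three
scales per trip (merging radii within 25% of a stronger peak) are
labelled 1st/2nd/3rd by descending radius.

Zone delineation thresholds the FPT series at the chosen scale r*. The
threshold — by tradition chosen by inspecting the FPT frequency
distribution — is automated: if log FPT is bimodal by Sarle's bimodality
coefficient (> 5/9, the uniform distribution's value; computed with the
finite-sample correction), the threshold is the Otsu two-class split of
log FPT, separating transit from search; otherwise the 75th percentile.
(A dip-test fallback would be the textbook choice for the unimodality
decision; the bimodality coefficient is used as a simple, dependency-free
criterion with a documented boundary.) Contiguous above-threshold runs
become zones carrying entry time, maximum residence (max FPT) and the
distance from the position of that maximum to the colony. For sea/land
ARS comparisons, mixed and island trips are dropped and sea trips must
reach at least 7.8 km (inclusive) — the direct distance a bird must
cover to reach the mainland anyway, so that both groups face comparable
minimum travel.

## Habitat selection

Mainland fixes at ≤ 10 km h⁻¹ (flight excluded) are binned into 500-m
cells anchored at the colony's projected origin (the origin is
configurable and reported, since spot counts can shift by ±1 cell under
translation). A cell where one trip's fixes span ≥ 30 min — last minus
first fix by default; a contiguous-run mode is available since "spent 30
min" is ambiguous between cumulative and contiguous — and hold at least
two fixes is a feeding spot. Individuals with more than 15 spots have
whole trips drawn at random (seeded) until the cap is reached, and the
most-dwelled spot per trip is flagged *primary*; selection tests use
primary spots.

Proportional use per habitat is (use share)/(availability share),
undefined at zero availability (such habitats are excluded from tests
and shown with a dash). Goodness-of-fit χ² = Σ(obsᵢ − n pᵢ)²/(n pᵢ) with
Monte-Carlo p-values: (1 + #{χ²_sim ≥ χ²_obs})/(n_sim + 1) over
multinomial(n, p) draws (the add-one estimator never returns exactly 0);
default n_sim = 10,000, and per-habitat tests use the two-cell
habitat-vs-rest form, skipped at availability ≤ 4. The grouped test
compares open-ground habitats (corn, potato, summer wheat, ploughed
soil, construction, water body, waste disposal) against ground-covering
vegetation. Pellet diet is summarized as frequency of occurrence:
100 × (pellets containing the item)/(pellets); items co-occur, so values
may sum above 100%.

## Isotope mixing

δX = (R_sample/R_standard − 1)·10³ in ‰ (¹³C vs V-PDB, ¹⁵N vs air N₂).
Plasma δ¹³C is lipid-normalized with the aquatic-animal calibration
δ¹³C_norm = δ¹³C − 3.32 + 0.99·C:N (red cells optionally, off by
default; a warning is raised above C:N = 10 where the linear form
extrapolates). Diet–tissue discrimination (0.7‰ C, 2.4‰ N) is subtracted
after normalization; corrected values are added as new columns, never
overwriting the raw ones, and a table-level guard prevents accidental
double application. Each individual's habitat use is the proportion of
its off-colony trip fixes classified marine; δ values are regressed on
that proportion with OLS per isotope × tissue (t = slope/SE on n − 2
df). Plasma integrates roughly the 3 days before sampling and red blood
cells 3–4 weeks.

## Synthetic colony (generator)

The generator emulates the data-generating process the analyses assume,
with one root seed split deterministically (seed + individual index for
tracks; fixed offsets for landscape, survey and isotopes), so identical
configurations give byte-identical outputs.

*Movement.* Each individual alternates colony dwell (position jitter
≤ ~50 m, speed < 3 km h⁻¹) with trips: a near-straight outbound leg at
commute speed (default 40 km h⁻¹ — an assumption; no flight-speed
distribution is available for the species) toward a destination drawn
around 30 km (sea trips N(30, 20²) km clipped to 4–75 km, land trips
N(30, 10²) clipped to 10–75 km: sea trips are twice as variable and may
be much shorter, matching the qualitative sea/land contrast of the study
system), a slow, tortuous search bout in a patch of radius
`patch_radius_km` at the destination, and a commute home. Headings
follow a wrapped-Cauchy turning distribution (concentration 0.97 on
commutes, 0.3 in patches). Within-patch search moves between waypoints
drawn uniformly in the patch disc, so the realized search area matches
the configured radius at any patch size (a purely diffusive walk cannot
fill a 10-km patch in a day). Land trips are scheduled entirely inside a
daylight window (04:00–22:00 local); sea trips start at any hour. The
device speed field is the true simulated speed plus N(0, 0.5 km h⁻¹)
noise, clipped at zero.

*Landscape.* The colony sits at the origin of a barrier island (±1.5 km
band); tidal flats span 1.5–9 km south; the mainland beyond 9 km south
is gridded into 500-m parcels whose habitat labels are drawn from the
configured availability mix (default: the 14-type agricultural mix of
the study landscape, grassland-dominated). North of the island is open
sea. The availability survey samples grid cells with replacement.

*Isotopes.* Two-endmember mixing:
δ = δ_land + p_sea (δ_sea − δ_land) + N(0, σ), independently per isotope
and tissue, with endmembers (−26, −17)‰ δ¹³C and (8, 15)‰ δ¹⁵N
(land, sea) and σ = 0.5‰ — values representative of terrestrial-
invertebrate vs marine-fish prey on the prey scale.

*What the generator does not emulate:* tides and tidal-flat foraging,
vessel-following behaviour (patches stand in for trawler aggregations),
wind, GPS position error, device failure, between-individual behavioural
specialization, and mean-level sea/land differences in trip metrics.
Passing tests therefore demonstrate that the analysis chain recovers
known structure from data obeying its assumptions — not that those
assumptions hold in any particular field dataset.

## Validation experiments

* *ARS scale recovery*: single-patch sea trips (destination 40 km,
  within-patch speed 12 km h⁻¹ — flight-based marine search between
  discard events, distinctly slower and more tortuous than the commute —
  residence 1 h per km of patch radius, scaling residence with patch
  crossing time). Over 20 seeded replicates per patch radius
  R ∈ {2, 5, 10} km, the median top variance-peak radius must fall in
  [R/2, 2R]; the fine grid serves patches ≤ 3 km, the coarse grid
  beyond. Detected scales run at roughly 0.6–1.5 R, the expected
  behaviour of the variance-peak method on disc-shaped patches.
* *Isotope slope recovery*: 200 replicate cohorts of 50 individuals with
  p_sea ~ U(0, 1) and σ = 0.5‰; the fitted plasma δ¹³C slope must lie
  within 2 SE of δ_sea − δ_land in ≥ 90% of replicates, and exactly
  at σ = 0.
* *Monte-Carlo p consistency*: on a 3-category toy table the simulated
  p at 100,000 replicates is compared with the exact multinomial tail
  obtained by full enumeration (|Δp| < 0.01).
* *FPT correctness*: closed form FPT = 2r/v on straight constant-speed
  paths to within spacing/v, and exact agreement (same interpolation
  rule) with an independent brute-force crossing search on random paths.

## Numerical choices and degenerate inputs

Duplicate timestamps keep the first fix; fixes implying > 150 km h⁻¹
from the previous retained fix are dropped (greedy single pass).
Zero-length path segments are removed before arc-length interpolation.
Variance of log FPT uses the unbiased (n−1) estimator. Summary SE is
reported as NaN for single-member groups. The Monte-Carlo χ² comparison
uses a 10⁻¹² tolerance on ties. Sub-seeds for stages and habitat tests
derive from CRC32 of the stage/habitat name plus the root seed, keeping
every seed below 2³¹.

## Known limitations

* The scale reported by the variance-peak method is a movement-defined
  scale, not the patch radius itself; it is only calibrated here to
  within a factor of two.
* The automated FPT threshold reproduces a conventionally subjective
  step; different reasonable automations (dip test + mixture split,
  fixed quantiles) shift zone counts by a few percent.
* Feeding-spot counts depend on the 500-m grid origin (±1 cell effects);
  the origin is fixed at the colony projection and reported.
* The land/sea mask is polygonal and static; tidal dynamics are ignored.
* With fewer than ~6 individuals the isotope regressions are structural
  only (df = n − 2 is tiny) — as in any small tracking cohort.
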