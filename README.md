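# suncache

Solar-referenced analysis of food-caching movement tracks in a
central-place-foraging rodent: a self-contained solar ephemeris, angular
track statistics, bimodality testing and two-component mixture modelling,
solar-arc recovery classification, mixed-model inference, and foraging-area
estimation — plus a seeded synthetic-data generator so the whole pipeline
is exercisable without any field data.

## What it does

1. **solar** — NOAA-style low-precision solar ephemeris (azimuth/elevation,
   sunrise/sunset at the −0.833° horizon, validated against an independent
   reference implementation to ≪0.5°), daily observation-period scheduling
   (daylight split into 5 equal intervals → 4 session start times), and the
   North–South mirror operation `az ↦ (360 − az) mod 360` that exploits the
   symmetry of the solar arc.
2. **tracks** — local equirectangular projection, start→stop bearings,
   path length and straightness index (Euclidean / path length), and the
   angle transform: signed offset of a track bearing from the solar
   azimuth (positive = right of the sun), folded about ±π/2 into
   [−π/2, π/2] so toward- and away-from-sun movements pool.
3. **diststats** — Hartigans' dip statistic (greatest-convex-minorant /
   least-concave-majorant algorithm; matches R's `diptest` to machine
   precision) with Monte-Carlo uniform-null p-values; two-component
   Gaussian mixture by multi-start EM; parametric-bootstrap standard
   errors; two-sample KS tests; skewness/kurtosis diagnostics.
4. **recovery** — PRE24/A24 classification of cache recoveries: compare
   the solar azimuth at recovery with the azimuth 24 h post-cache (θ_a)
   and its North–South mirror (θ_b); azimuthal error metrics; the Yates
   continuity-corrected equality-of-proportions test; theft summaries.
5. **inference** — linear mixed models (subject nested in group as random
   intercepts; statsmodels backend, log-likelihoods cross-checked against
   lme4) with ML likelihood-ratio tests, and the full named model suite
   (track direction vs sun azimuth, offsets vs observation period, cache
   survival vs group size, recovery vs cache azimuth, error models, hull
   vs null area).
6. **area** — alpha-shape foraging areas (Delaunay circumradius filter at
   the minimal alpha covering all points, convex-hull fallback) versus the
   null circle through the farthest start point; CSV + GeoJSON output.
7. **synth** — seeded generator emitting the exact CSV dialects the
   readers consume plus a latent-truth JSON: bimodal solar-offset bearings,
   tunable straightness, GPS noise, group-size-dependent theft hazard, and
   recoveries placed at the +24 h instant or the same-azimuth mirror
   instant (solved on the ephemeris by bisection).
8. **cli** — `suncache` command with subcommands
   `sun · synth · tracks · fit · recovery · models · area · all`.

## CLI quick start

```sh
# generate a synthetic dataset
suncache synth --seed 1 --out data/

# run the whole pipeline (dip test, mixture fit + bootstrap SEs,
# recovery classification, model suite, areas, combined report)
suncache all --fixes data/fixes.csv --events data/events.csv \
    --truth data/truth.json --seed 1 --out results/run1

# solar position lookup
suncache sun --time 2014-06-21T10:00:00Z
```

Every pipeline run writes a `manifest.json` (config hash, seed, version);
identical seeds give byte-identical reports.

## Layout

```
src/suncache/         one module per pipeline stage (see above)
tests/                pytest suite; test_acceptance.py holds the
                      acceptance criteria; reference_ephemeris.py is the
                      independent solar oracle used only by tests
scripts/acceptance.py acceptance-target report
```
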