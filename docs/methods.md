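# Methods

This note records the models implemented in `termd`, the assumptions behind
them, the tunable parameters with their defaults, and what the synthetic data
do and do not establish about real measurements.

## Circular-genome model and rearrangements

The chromosome is a ring of `length_bp` 1-based positions (default 4,641,652,
the E. coli K-12 MG1655 length).  Regions tile the circle; a region given
borders `(start, end)` owns the half-open ascending arc `(start, end]`, so
adjacent regions share border coordinates and wrap-around regions (the Ori
macrodomain) are handled uniformly.  Features are zero-length points;
recombination-site turnover (attB → attL′/attR′) is feature relabelling, not
sequence editing — the genome is a coordinate model, sequences live in the
motif scanner.

**Transposition** excises the ascending arc `(attR, attL]` and reinserts it
immediately after `attB′`, preserving internal orientation.  This single
convention (excised arc runs ascending from attR to attL) reproduces all
seven published rearranged-strain configurations from one wild-type tiling.
Reinsertion into the excised arc is rejected, as are coincident att
positions.  **Inversion** reverses an ascending arc in place and flips
strands inside it.  Both return a `CoordinateMap`, an exact piecewise
bijection old→new; property tests check bijectivity, length conservation and
inverse-composition identity on random genomes.  New coordinates are anchored
so old position 1 keeps coordinate 1 whenever it survives outside the excised
arc.

**Configuration strings** list region labels clockwise from the Ori region.
Rearrangements split regions into pieces; following the conventions of
published strain tables, pieces shorter than 100 kb (configurable) are left
out of the *string* (they remain in the genome), a region surviving as one
displayed piece keeps its bare label, and a region displayed as several
pieces annotates each with its original kb span, e.g. `Right(914-1135)`.
This one rule reproduces the published annotations, including their silent
dropping of ≤51-kb remnants.

**Region borders.**  Only a handful of border coordinates are fixed by the
engineered att sites (653/1135/1920 kb region boundaries and the 600–806 kb
Right-MD interval quoted with the deletion-mapping strains); the remaining
defaults (Ori 3697.8–130 kb wrapping, NSR to 600 kb, NSL to 3697.8 kb) are
reconstructions and are configurable per strain config.  Likewise the parS
marker coordinates are approximate positions read off the genetic-map axes;
the strain panel only depends on their order relative to the insulators and
borders.

## Insulation rule engine

Genotype flags: `matP`, `zapB`, `yfbV`, plus the optional modifier `yihI`.
Cell-cycle stage is binary: `ANCHORED` (Ter macrodomain tethered to the
divisome at mid-cell, by default the second half of the cycle) or
`PRE_ANCHORING` (small cells).

* A **functional insulator** is an insulator feature whose 12-base sequence
  matches the IUPAC consensus `GYTGACGTCAGC` with zero mismatches, in a
  `yfbV+` background.  The shuffled palindrome `GACGCTAGCGTC` (8 mismatches)
  is the packaged negative control.
* The **constraining process** runs only when `matP` and `zapB` are present
  and the stage is `ANCHORED`.  From each Ter border it walks away from Ter
  until the first functional insulator (blocked *at* the insulator
  coordinate: a marker exactly on the insulator is outside) or, failing
  that, the Ori-macrodomain boundary.  Stopping at Ori is a model
  assumption — Ori markers are unaffected in every construct modelled, but
  nothing in the data identifies the actual stop; `spread_bounded_by_ori`
  can be switched off to let the walk run the full circle.
* **Classification**: Ter markers are `TER_ANCHORED` / `TER_STRUCTURED` /
  `FREE` as MatP/ZapB/stage dictate; non-Ter markers are `CONSTRAINED`
  inside a spread interval, otherwise `STRUCTURED` in a macrodomain and
  `FREE` in an NS region.  `yihI−` releases Right/Left (not Ori)
  structuring to `FREE`, making the spread visible inside those
  macrodomains; off by default.

`CONSTRAINED` and `STRUCTURED` share motion parameters deliberately: the
spread's reach through the Right/Left macrodomains is invisible in mobility
data precisely because macrodomain loci are already slow.  The packaged
expectation table therefore records `CONSTRAINED` for macrodomain markers
inside a spread interval (e.g. Right-2 with tidR deleted) even though the
corresponding figure panels show "unchanged" bars.  The model also keeps
`CONSTRAINED` deliberately uncoupled from spatial co-localization with the
Ter focus: constrained NS regions are *not* recruited into the MatP
territory, so no positional coupling is simulated.

The expectation table (~90 rows) transcribes every informative strain ×
marker × stage phenotype from the mobility and segregation panels of the
source study; the rule engine reproduces it exactly, and the monotonicity
property (adding a functional insulator can only shrink spread intervals)
holds by construction and is property-tested.

## Motif scanning

Mismatches are counted against the degenerate consensus (a base failing its
IUPAC class costs 1; degenerate positions accept their class at no cost;
non-ACGT bases in the subject always count as mismatches).  A "distance from
tidR" mode (literal pattern `GCTGACGTCAGC`) is exposed as well, because
published per-genome censuses can be phrased either way; the `census` helper
reports exact and ≤1-mismatch counts under both conventions, with and without
palindromic collapsing, rather than guessing which convention a given count
used.  Scanning is vectorised (per-position 256-entry lookup tables summed
over the 12 offsets), supports circular windows across the origin, and
reverse-strand hits are found by scanning the reverse-complemented pattern so
every hit is reported at its forward-strand window start.  The scanner is
validated against an exhaustive window-by-window oracle on random sequences
for budgets 0–2.

## Trajectory simulator

Motion is 2-D Brownian with per-axis increment variance `2·D·dt`, confined by
a reflecting circular boundary of radius `r_c` about the class home position,
plus independent Gaussian localization noise `sigma_loc` per frame.  The
reflected disc was chosen over a harmonic (OU) trap for its simpler contract
(hard support, exact uniform stationary distribution); an OU variant with
matched stationary spread (s.d. `r_c/2`) is available via `model="ou"`.
Imaging defaults follow the tracking protocol: `dt=10 s`, 31 frames (5 min),
30 foci per group.

Closed forms used as oracles: unconfined mean step length
`sqrt(pi*D*dt)` (Rayleigh), hence expected travelled distance
`30*sqrt(pi*D*dt)`; long-lag MSD under confinement bounded by `(2*r_c)^2`
(uniform-disc value `r_c^2`); pure-noise MSD flat at `4*sigma_loc^2`.

**Class calibration.**  Mean step length scales as `sqrt(D)`, so a
2–3-fold travelled-distance contrast between free and macrodomain loci — the
contrast the source mobility data show — requires class D values spanning
roughly an order of magnitude, not a factor 2.  Defaults: FREE `D=1e-3`
µm²/s, `r_c=0.45` µm; STRUCTURED/CONSTRAINED `1.5e-4`, `0.22`;
TER_STRUCTURED `8e-5`, `0.18`; TER_ANCHORED `5e-5`, `0.12`, all with
`sigma_loc=0.02` µm (typical GFP-spot precision; a larger noise floor
compresses the class contrast).  Ter classes sit at mid-cell
(`center=0.5`), others at the cell quarters, matching the home positions at
which mobility is conventionally measured.  The source study reports
mobility only as figure bars without printed µm values, so these absolute
numbers are calibrations, not published values; only the orderings and
ratios are meaningful.

## Population simulator

Cell ages are drawn from the steady-state exponential age distribution
`(2 ln2/τ)·2^(−a/τ)` on `[0, τ)` (inverse-CDF sampling, Kolmogorov–Smirnov
tested).  A locus at relative replichore position `m` (0 at oriC, 1 at the
terminus; computed from post-rearrangement coordinates, so transpositions
change gene dosage) is passed by a fork `X = C·(1−m) + D` minutes before
each division; its copy number at age `a` is `2^floor((X+a)/τ)`, which
handles overlapping replication rounds and integrates to the Cooper–
Helmstetter average `2^(X/τ)` — the identity used both as `nb_th` and as a
simulation oracle.  Time since the latest passage is `(X+a) mod τ`.

Sister pairs from the latest passage are reported as one focus while that
time is below the class cohesion time (defaults: 0 for FREE, `0.5·τ` for
STRUCTURED/CONSTRAINED, `0.6·τ` for Ter classes).  Resolved sisters separate
by a class separation distance (0.5 µm; 0 for Ter classes, whose sisters
remain at mid-cell), positions are scattered (s.d. 0.08 µm) about the
quarter/mid-cell anchors, and any two foci closer than the merge radius
(0.25 µm, diffraction scale) are merged.  Schedule edge cases (replication
exactly at birth, `C+D` a multiple of `τ`) resolve by half-open age
intervals `[birth, division)`.

Under the default calibrated conditions (τ=30, C=40, D=20 min, `m=0.35`,
2000 cells) this yields a co-localization index ≈ 0.30 for a
macrodomain-class marker and ≈ 0 (|index| ≤ 0.02) for an NS-class marker,
on either side of the published class bounds (>0.1 vs <0.02), with the Ter
marker highest (≈ 0.37) — the index ordering Ter > MD > NS.  Exact published
index decimals and bar heights derive from real microscopy and are not
reproduction targets; the acceptance surface is the printed bounds and the
orderings.

## Statistics

* **Travelled distance**: sum of per-interval Euclidean step lengths on raw
  focus coordinates (matching the summation definition); an optional
  cell-frame mode projects onto the pole-to-pole axis for drift-prone
  inputs.  Non-uniform frame intervals warn but compute.
* **Apparent diffusion**: time-averaged MSD, least-squares `MSD = 4·D·τ + b`
  on lags 1–4 with intercept, since the estimator behind published
  diffusion-coefficient tables is unstated; the intercept absorbs the
  localization-noise floor.  Confinement biases `D_app` below the true D for
  fast loci — a bias real tracking data share.
* **Group summary**: sample mean and s.d. (n−1), warning when n deviates
  from the 30-focus convention.
* **Co-localization index**: `(nb_th − nb_obs)/nb_th` exactly;
  `index + nb_obs/nb_th = 1` is asserted as an identity.
* **Interfocal distances**: Euclidean, 0.1-µm bins, with the fraction
  < 0.4 µm and > 0.3 µm reported (the two published headline thresholds).
* **Mobility comparison**: Welch's t-test plus mean ratio (the original
  comparisons were visual; the formal test is an addition), cross-checked
  against an exhaustive permutation test at small n.

## Determinism and problem sizes

Every stochastic routine takes one integer seed and produces bit-identical
output on reruns.  Default test/acceptance problem sizes — 300 trajectories
for the travelled-distance closed form, 100 for D recovery, 2000 cells for
population means and index bounds, 5-kb sequences for scanner-vs-oracle —
were chosen so each Monte-Carlo check resolves its 3-standard-error (or 10%)
tolerance comfortably; the entire suite runs in a few seconds on one CPU.

## Known limitations

* No molecular mechanism of the spreading process is modelled (tracking
  factor vs mechanical change — deliberately left open), and no polymer
  physics; classes map to phenomenological motion/cohesion parameters only.
* No image formation or spot detection: foci are point observations, the
  tracking layer (ImageJ-style) is out of scope, coordinates are the
  interface.
* The genome census of tidRL-like sites needs the actual chromosome sequence
  (e.g. GenBank U00096) as FASTA input; the package ships only planted
  synthetic sequences, so the census API is exercised on those.
* Marker coordinates and non-att region borders are reconstructions (see
  above); conclusions that depend on exact marker-to-insulator distances
  rather than order should re-specify them from primary coordinates.
* Passing the packaged tests shows the implementation is internally
  consistent and matches the stated closed forms and transcribed phenotypes;
  it does not validate the biological model against new experimental data.
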