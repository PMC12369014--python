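# Methods

## Scope and model chain

`bacadhere` models phase-one (quasistatic) bacterial adhesion on soft
polymer films — the regime in which attachment is governed by the
instantaneous energetic compatibility of a single bacterium-surface
contact, before any biofilm maturation. Three linked components:

1. a **JKR-Griffith threshold model** mapping substrate mechanics to an
   adhesion energy barrier,
2. a **stochastic lattice simulation** in which each contact event
   succeeds or fails by comparing a sampled xDLVO interaction energy
   against that barrier, and
3. an **SEM morphometry pipeline** that quantifies adhesion outcomes in
   micrographs, validated here against a ground-truthed synthetic image
   generator.

## Adhesion threshold model

A spherical bacterium on a compliant film forms a JKR adhesive contact.
Combining the JKR contact solution with a Griffith energy balance yields
a critical contact radius

    a_c = (9 pi dg R^2 / (2 E*))^(1/3)

with `E*` the effective elastic modulus (Pa), `dg` the work of adhesion
(J/m^2), and `R` the effective contact radius (m). The threshold energy
is taken as the interfacial energy released over the critical contact
disc,

    U_th = -pi a_c^2 dg,

the simplest Griffith-consistent closed form; it scales exactly as
`E*^(-2/3)` and `dg^(5/3)`, the two power laws that separate the film
conditions. Thresholds are stored as negative energies; "lower barrier"
means less negative.

**Defaults.** Two film conditions ship as constants: hydro-softened
(`E* = 1.8 MPa`, `dg = 1.5 J/m^2`) and unsoftened (`E* = 85 MPa`,
`dg = 6.4 J/m^2`). `R` is not directly measurable and is treated as a
per-substrate calibration constant: `R = 0.104 um` (hydro-softened) and
`R = 0.145 um` (unsoftened) are back-solved so the closed form lands on
reference thresholds of −1.2×10⁻¹² J and −1.6×10⁻¹² J. The two
reference thresholds are not consistent with a single `R` under a pure
power law, which is why `R` is substrate-specific.

## xDLVO interaction energies

Total bacterium-plate interaction energy is the sum of the standard
sphere-plate expressions: Lifshitz-van der Waals `−A_H R_b / 6h`,
constant-potential electrostatic double layer (potentials `psi_b`,
`psi_s`, inverse Debye length `kappa`), and an exponentially decaying
Lewis acid-base term anchored at the `h0 = 0.157 nm` contact-minimum
convention. Defaults are literature-typical for a ~0.8 um gram-positive
coccus in physiological buffer (`A_H = 1e-20 J`, `psi = −30/−20 mV`,
Debye length ~0.77 nm, `dG_AB(h0) = −5 mJ/m^2`, `lambda_AB = 0.6 nm`);
every value is overridable. `secondary_minimum` locates the shallow
attractive well beyond the electrostatic barrier by a dense grid scan
plus bounded refinement, returning `None` for monotone profiles.

**Per-contact sampler.** The simulation does not integrate the profile
per event. The total interaction energy of one stochastic encounter is
modelled as Gaussian with a single `(mu, sigma)` shared across
substrates, so film condition enters only through its threshold.
`calibrate_sampler` solves the two normal-quantile equations
`Phi((U_th − mu)/sigma) = p` for the pair of target per-contact adhesion
probabilities. The shipped default is calibrated against the thresholds
of the two default substrates at targets `(0.1782, 0.0321)`, giving
`mu = −0.7925e−12 J`, `sigma = 0.4345e−12 J`. Those targets are the
calibration constants that make the default attempt schedule (below)
yield 24 h expectations of ~1000 and ~180 adhered bacteria.

## Stochastic grid simulation

Adhesion is simulated on a binary `1024 x 1024` lattice. The planktonic
population follows logistic growth
`N(t) = K / (1 + ((K−N0)/N0) e^{−rt})` with defaults `N0 = 100`,
`K = 2000`, `r = 0.3 /h` — calibration constants chosen so the attempt
total over the four time points is ~5614. At each time point
(6, 12, 18, 24 h) the simulator performs `round(N(t))` fresh contact
attempts (not the cumulative population — the simplest monotone
bookkeeping); each draws one energy and succeeds iff it is at or below
the substrate threshold; each success seeds one bacterium at a uniformly
random unoccupied cell. Occupied-cell draws are resampled (collisions
are negligible at ~10³ occupants of 2²⁰ cells); a bounded retry count
(1000) guards pathological saturation, after which the event is dropped
with a warning. Counts are cumulative and non-decreasing.

Ensembles run `n_reps = 8` replicates on independent substreams spawned
from one master seed (`numpy.random.SeedSequence`), so results are
bit-reproducible per seed and replicates are statistically independent.
Per replicate the 24 h count is binomial-like: expectation
`n_att * p ≈ 1000.4` (soft) and `180.2` (unsoftened), SD ~29 and ~13,
so the 8-replicate ensemble mean carries a standard error of ~10 and ~5
counts. The fold change is the ratio of 24 h ensemble means, expected
~5.6.

## SEM quantification pipeline

Stages, each exposed separately and chained by `quantify_image`:

- **preprocess** — CLAHE (clip limit 0.01), Gaussian smoothing
  (`sigma = 1 px`), background estimation by grayscale opening with an
  81-px square window, subtraction, clip to [0, 1]. The output is *not*
  re-scaled to full range after subtraction: max-normalising a blank
  field would amplify its own noise into spurious foreground.
- **binarize** — local-mean adaptive threshold (window 51 px) with an
  additive offset margin of 0.15: after CLAHE the background noise SD on
  the local-mean scale is ~0.05 at the generator's default noise while
  particle contrast is ~0.6, so 0.15 sits ~3 noise SDs above background
  and ~4x below signal. Regions under `min_area = 30 px` are removed.
- **split_touching** — Euclidean distance transform, peak markers with a
  minimum separation (`min_distance = 7 px`, at least one marker per
  component), marker-controlled watershed. Every foreground pixel gets
  exactly one label.
- **measure** — per-object area, perimeter, circularity `4 pi A / P^2`,
  solidity (area / convex-hull area) and centroid, after a small
  morphological closing (radius 1) smooths each object mask.
- **classify** — single iff `area <= 1.5x` the nominal cell
  cross-section (0.503 um^2 for a 0.8 um coccus) AND circularity >= 0.7
  AND solidity >= 0.9; thresholds inclusive, expressed in um^2 so the
  rule is pixel-scale invariant.
- **summarize** — class counts, fractional coverage, and
  `scaled_count = coverage / 7.7e-5`, the mean surface fraction occupied
  by one bacterium (0.0077%).

**Counting convention.** Object counting and classification operate on
connected components: an aggregate is one (multi-cell) object. The
watershed split is exposed for resolving constituent cells inside
aggregates, not applied in the default counting path — applying it there
would dissolve every aggregate into cell-sized, round fragments and
erase the single/aggregate distinction.

## Synthetic micrograph generator

Cocci are rendered as anti-aliased bright discs (0.8 um diameter at
0.05 um/px, ~200 px^2) on a 0.2-level background at 0.9 foreground
level, on a 1024 x 1024 field matching the simulation lattice. Defaults:
50 singles and 10 clusters of 3-6 cells (cells packed at 1.0-1.3 radii
from an existing member), 5% of singles placed as touching pairs at
1.6 radii separation, additive linear illumination ramp of amplitude
0.1, Gaussian noise SD 0.05, clipped to [0, 1]. Exact ground truth
(classes, centroids, cell counts, noiseless-mask coverage) accompanies
every image.

What the generator does *not* emulate: SEM charging and astigmatism,
textured film background, partial focus, rods, or dense lawns. Passing
the recovery tests therefore demonstrates the pipeline's correctness on
well-separated, disc-like particles with smooth illumination — not its
robustness to every real-SEM artifact; on real micrographs the
configurable thresholds are expected to need re-tuning.

A deliberate consequence of the touching-pair condition: the two members
of a fused pair are detected as one aggregate-classified object, so with
defaults the expected detection is 59 of 60 objects (1.7% undercount)
and 48 of 50 singles recovered as singles — within the 10% count and 90%
classification tolerances the recovery tests assert.

## Statistics

`ttest_ind` implements the pooled-variance Student test (default;
Welch optional) — pooled because the comparisons target balanced small-n
designs. `anova_two_way` implements the balanced two-way ANOVA with
interaction directly from the cell-mean sums-of-squares algebra and
refuses unbalanced layouts rather than silently choosing a
sums-of-squares type; for balanced data the sequential decomposition is
order-free. Degenerate cases: zero variance in both t-test groups gives
`p = 1` (equal means) or the `p -> 0` limit (unequal); constant ANOVA
data gives all-zero SS with undefined F. Reference distributions (t, F)
come from scipy.

## Numerical and testing choices

- All energies in joules end to end; `to_kT` is display-only.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  ensemble substreams come from `SeedSequence.spawn`.
- The test suite checks each closed form against an independent oracle:
  the cube identity for `a_c`, brute-force argmin for the secondary
  minimum, Monte-Carlo frequencies for the calibrated sampler, binomial
  expectations for the simulator (via common-random-number replays for
  threshold monotonicity), explicit projection algebra and statsmodels
  for the ANOVA, and generator ground truth for the image pipeline.
- Problem sizes in the default suite: full-size ensembles (1024^2, n=8)
  for the headline means; a 256^2 lattice with 200 replicates for the
  binomial-convergence property; 20 full-size synthetic micrographs for
  recovery.

## Known limitations

- The threshold prefactor (`-pi a_c^2 dg`) is a modelling choice
  constrained by the two power laws and the two reference energies, not
  a derived uniqueness result.
- No detachment, no cell-cell interaction on the lattice, no biofilm
  phase; the simulation is quasistatic by construction.
- The Gaussian per-contact energy model is a calibration device; its
  (mu, sigma) are not measurements of a physical energy distribution.
- Pixel-scale classification defaults assume ~0.05 um/px imaging of
  ~0.8 um cocci; other organisms or magnifications require re-tuning
  `area_single_max_um2` and the segmentation windows.
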