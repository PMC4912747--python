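# Methods

This note records the models behind each module, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests
do and do not demonstrate about real measurements.

## BMP gas accounting and degradation statistics

A batch test bottle (309 mL serum bottle, 193 mL liquid, hence 116 mL
headspace by default) produces gas that is tracked by headspace
overpressure readings plus GC methane fractions. The accounting assumes
the bottle is vented back to the reference pressure (1 bar) after every
sampling, so each reading is the overpressure accumulated over one
interval; the interval's gas volume at incubation conditions is
`headspace · ΔP / P_ref`, its methane share the interval CH₄ fraction, and
the volume is normalised to 273.15 K / 1 bar with the ideal gas law.
Negative readings are treated as measurement anomalies: the interval
contributes zero gas (keeping per-bottle cumulative curves non-decreasing)
and readings below −0.02 bar additionally raise a warning. This venting
convention is one defensible reading of a manual pressure-measurement
protocol; a sensor that integrates pressure without venting would need a
different interval definition.

Control (inoculum-only) bottles measure endogenous methane. The net
specific curve is `mean over test replicates of (test − mean control)`,
divided by the substrate volatile solids (3 g VS L⁻¹ × 0.193 L = 0.579 g
in the reference geometry). No inoculum-amount scaling is applied because
controls receive the same inoculum volume as tests. Negative net
increments are retained, not clamped — after control subtraction a net
curve may dip locally, and hiding that would hide anomalies.

The **final potential** is the value at the last sampling day, not a
fitted asymptote: the summary statistics of interest are empirical day
counts, and fitting would entangle them with a model choice. **T50/T80**
use the first sampled day at or above the threshold, matching whole-day
reporting; linear interpolation between the bracketing samples is
available behind a flag but is not the default. **Degradation
performance** is 1/T50 and 1/T80 (day⁻¹), the form used as an ordination
constraint (larger = faster).

## Free ammonia

Free ammonia follows the NH₄⁺/NH₃ equilibrium with the
temperature-dependent dissociation constant of Hansen, Angelidaki & Ahring
(1998): `pKa(T) = 0.09018 + 2729.92 / T_K`. TAN is interpreted as g N L⁻¹
and free ammonia reported on the same nitrogen basis (no N→NH₃ mass
conversion); this matches the magnitudes of the bundled operating table.
Of the ten reference rows, only CD03, WWTP04, WWTP05 and WWTP06 recompute
exactly (3 d.p.) from their printed TAN/pH/temperature; the remaining rows
were evidently derived from unrounded instrument values, so the tests pin
only the four reproducible rows. `annotate_records` never drops a row:
missing inputs are flagged and below-detection sentinels (e.g. `"<0.1"`
VFA entries) pass through verbatim.

## T-RFLP processing

The background rule — peaks below the gene-specific size floor (70 bp
*cel5*, 50 bp *cel48*) and peaks under 1 % of total area are background —
is grammatically ambiguous between a conjunctive and a disjunctive
reading. The default is **disjunctive** (drop if either criterion fails),
because published profiles contain neither sub-floor nor sub-1 % T-RFs;
`combine="and"` gives the conjunctive reading. The 1 % share is always
measured against the **pre-filter** total area, since "background" is a
property of the raw trace; surviving peaks are renormalised so profiles
sum to 1. Peaks outside the 50–500 bp calibration range of the GS ROX 500
size standard are unreliable and always dropped.

Cross-sample binning is greedy: the heaviest unassigned peak (by total
abundance across samples) seeds a bin that captures all peaks within the
tolerance (default 1.0 bp, so a bin spans at most 2 bp); the label is the
abundance-weighted mean size rounded to an integer. Greedy seeding by mass
makes the procedure deterministic and insensitive to sample order;
fragment sizes are reported as integers, and no published binning
procedure exists to mirror, so this is a package design choice.

## In-silico digestion

Fragment length counts the labelled-strand nucleotides 5′ of the cut,
including the labelled primer itself (the fluorophore sits on the primer's
5′ end): a site whose recognition sequence starts at 0-based index *i*
with cut offset *c* yields a fragment of *i + c* nucleotides. The default
is **double-digest semantics** — the minimum fragment over MboI and AluI —
because both enzymes are used on the amplicon pool; passing a single
enzyme gives single-digest semantics, since assigning one enzyme per
marker gene is an equally plausible protocol reading. Site-free amplicons
return their full length flagged `uncut`.

Orientation accepts clones deposited on either strand: the labelled
primer is searched (IUPAC-degenerate, ≤ 2 mismatches by default, up to
5 bp of 5′ slack) near the 5′ end of the sequence and of its reverse
complement. Degeneracy is honoured in primer matching only — digest
targets are concrete sequences, so recognition sites are plain ACGT.
Observed-to-predicted matching uses ±2 bp by default, absorbing
electrophoretic-mobility offsets, and is one-to-many on purpose: distinct
sequences can share a T-RF size, and collapsing such ties would
overstate the fingerprint's resolution.

## Alpha diversity

Replicate libraries are pooled by element-wise summation before rarefying.
Rarefying draws **without replacement** (multivariate hypergeometric), so
a subsample is a true subset of reads and totals are exact. Chao1 defaults
to the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, which is defined
when no doubletons exist; the classic `S_obs + F1²/(2F2)` is behind a
flag. Shannon defaults to **base 2**: the bundled panel's values (e.g.
5.899 with 244 OTUs) exceed the natural-log ceiling ln(244) ≈ 5.50 but fit
the base-2 ceiling log₂(244) ≈ 7.93, so bits are the convention that makes
the panel internally consistent; natural log is available via `base`.
Coverage is 100·S_obs/Chao1 reported at 1 d.p. (With printed integer
Chao1 values, recomputed coverage can differ from an originally reported
bound by 0.1 — e.g. 135/209 gives 64.6 %.)

## Ordination and resampling

**UniFrac.** Unweighted: unique branch length over the branch length
leading to taxa observed in either community (the original definition);
weighted: Σ bᵢ·|p_iA − p_iB|, normalised by Σ bᵢ·(p_iA + p_iB) to lie in
[0, 1]. Implemented by a single post-order traversal; newick parsing is
delegated to scikit-bio's `TreeNode`. Every non-zero taxon must be a tree
tip — a missing taxon is an error naming the id, never silently ignored.

**PCoA.** Gower double-centering of −d²/2 and an eigendecomposition;
coordinates are eigenvectors scaled by √eigenvalue for positive
eigenvalues. Negative eigenvalues (non-Euclidean input) are reported but
not corrected (no Cailliez/Lingoes), because only the top positive axes
are plotted.

**CCA.** The ter Braak algorithm: chi-square residuals
`(P − rcᵀ)/√(rcᵀ)` of the relative community matrix are projected onto the
row-mass-weighted, centred and scaled constraints via QR, and the fitted
part is decomposed by SVD. Total inertia is the community chi-square
statistic over the grand total; constrained eigenvalues lie in [0, 1] and
sum to at most the total inertia. Scores follow scaling type 2 (feature
scores in principal coordinates, LC site scores standard, biplot scores as
weighted correlations with the LC axes), the common default of ecological
ordination software; the implementation reproduces the vegan package's
eigenvalues and biplot scores to ≥ 6 decimals on test fixtures. Constant
or collinear constraint columns (QR rank test at 1e-10) raise an explicit
error rather than being absorbed by a pseudo-inverse. Community input is
used as-is (counts or relative abundances; the chi-square standardisation
makes the analysis scale-invariant per sample), with a ≥ 2 % inclusive
major-feature filter available for restricting to dominant taxa.

**Permutation test.** Statistic: pooled-variance two-sample t on the
original labels; p = (1 + #{|t*| ≥ |t|}) / (B + 1) over B seeded label
shuffles (add-one estimator, so p is never 0 and the floor at B = 999 is
0.001). Ties are counted, including the ±∞ statistics that arise when
both groups are internally constant: a relabelling that reproduces the
exact split ties the observed statistic, so for tiny groups (3 vs 3) the
smallest attainable p is ≈ 2/C(6,3) = 0.1, not 1/(B+1) — the floor is only
reachable when group sizes make exact-split permutations negligible. Both
groups constant **and** equal is degenerate: p = 1 is returned flagged.

## Synthetic-data generators

The generators emulate the study conditions, not the instruments:

* **BMP**: modified Gompertz curves, `M(t) = P·exp(−exp((Rmax·e/P)(λ−t)+1))`,
  the standard saturating form for batch methane production (the analytic
  half-potential time is λ + (1 − ln ln 2)·P/(Rmax·e)); defaults P = 350
  N mL g VS⁻¹, Rmax = 50 N mL g VS⁻¹ d⁻¹, λ = 2 d, daily sampling over 60
  days, triplicates — a cellulose-like, well-running test. A first-order
  exponential core is available. Test bottles include the endogenous
  contribution (default 10 % of P) on top of the substrate curve, controls
  only the endogenous part, so subtraction recovers the substrate curve.
  Noise is i.i.d. Gaussian on the cumulative volume, truncated at zero —
  the simplest model consistent with per-interval pressure readings; it
  ignores autocorrelation from venting errors.
* **Electropherograms**: one peak per true T-RF with area ∝ share,
  Gaussian size jitter, and baseline peaks placed uniformly on 50–500 bp
  but ≥ 3 bp away from any true T-RF, each strictly below 1 % of total
  area. The exclusion gap makes filter tests unambiguous; real baselines
  can sit under true peaks, which these tests do not probe.
* **Amplicons**: uniform-random ACGT with all recognition sites scrubbed
  by local resampling, then one site planted at the requested offset; the
  construction is verified so the planted cut is provably the first.
* **OTU tables**: per-sample lognormal relative abundances (σ = 0 gives an
  even community with closed-form Shannon log₂K and Simpson 1 − 1/K),
  multinomial sampling at fixed depth (default 2500 reads, the survey's
  rarefaction depth).

Each generator is a pure function of its spec; all randomness flows from
the spec's single integer seed. Passing tests on these inputs shows the
estimators are correct under the stated models; it does not validate
against sequencing error, chimeras, PCR bias or peak-calling artefacts,
which are outside the package's scope.

## Problem sizes in the automated checks

The acceptance script exercises a 20-point noiseless kinetics grid, 200
noisy kinetic replicates, 1000 random amplicons against the brute-force
digestion oracle, eight 2500-read even communities, and 1000 simulated
null datasets at 199 permutations for the test-calibration check (999 for
the p-floor check) — sizes at which every Monte-Carlo margin used in the
assertions is comfortable while the whole run stays in seconds.

## Known limitations

* The BMP venting convention and the Gompertz simulator core are modelling
  choices; neither is inferred from deposited raw gas data.
* T-RF binning is a deterministic greedy heuristic, not an optimal
  clustering; bins never exceed 2×tolerance in width but labels can shift
  by 1 bp under adversarial size distributions.
* CCA axis significance testing (permutation of constraints) is not
  implemented.
* UniFrac expects a rooted tree with branch lengths; zero-length branches
  contribute nothing to either numerator or denominator.
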