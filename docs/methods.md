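# Methods

`maplink` re-implements, as a reusable and tested pipeline, an integrative
modeling procedure for localizing protein subunits in a cryo-EM density
map: per-subunit rigid-body fit libraries filtered by envelope coverage, a
simultaneous simulated-annealing Monte Carlo assembly under chemical
cross-link restraints, and a validation layer. This note records the
model, its assumptions, the tunable parameters, and the design choices
made where the procedure it models leaves the details open.

## Geometry and map conventions

Coordinates are Cartesian Å throughout. Density maps are regular grids of
isotropic voxels; voxel `(i, j, k)` is *centered* at
`origin + voxel_size · (i, j, k)` with logical axis order X, Y, Z (axis 0
= X). MRC/CCP4 files with permuted `MAPC/MAPR/MAPS` headers are
re-indexed on read so that world coordinates are preserved; only
real-valued modes are supported, and maps are written as mode 2 with the
`ORIGIN` header set. Residues are addressed `(chain_id, residue_number)`
in author numbering; insertion codes are rejected because cross-link
tables address residues this way and an ambiguous key would corrupt the
restraint mapping. Occupancy and B-factor are preserved on IO but never
enter any score.

## Density simulation and correlation scoring

Model density is a sum of isotropic Gaussians, one per atom, with
amplitude proportional to the atom weight (atomic number; uniform for
CA-only coarse models, adequate in the 6–10 Å regime this pipeline
targets) and width

    sigma = resolution / (pi · sqrt(2)),

a widely used map-simulation convention. Gaussians are truncated at
4.5 sigma; the analytic mass integral `sum(w) · (2·pi·sigma²)^{3/2}` is
reproduced to <1% at adequate padding, which the tests assert.

The fit score of a placement is the whole-grid Pearson correlation
between this Gaussian model density and the target map. It is evaluated
in closed form rather than by building a grid per trial placement:
writing the simulated density as a sum of atom Gaussians, the model–map
cross term equals the Gaussian-smoothed target map interpolated at the
atom positions, and the model self term is the analytic pairwise Gaussian
overlap `sum_ij w_i w_j exp(-d_ij²/(4 sigma²)) (pi sigma²)^{3/2}`, which
is invariant under rigid motion. One scorer therefore smooths the target
once, and each trial placement costs O(atoms). The closed form agrees
with the direct route (simulate on the grid, then Pearson) to within
discretization error (~1e-2 on the test fixtures, tighter at finer
voxels); the agreement is a dual-route test, and the exact grid-space
Pearson (`cross_correlation`) is itself verified against a per-voxel
brute-force loop at 1e-6.

## Envelope threshold and coverage

The map *envelope* is the region at or above a low-density threshold.
Because the modeled protocol does not state its threshold, the default is
volume-based: the threshold at which the enclosed volume equals
`1.5 × mass × 1.21 Å³/Da` (the conventional protein partial volume,
inflated 1.5× to a generous low contour). A fixed value can be supplied
instead; without a mass the fallback is 5% of the map maximum. *Envelope
coverage* of a placement is the fraction of atoms whose trilinearly
interpolated map value reaches the threshold; atoms outside the grid
count as uncovered.

## Fit libraries

`build_fit_library` proposes `n_searches` placements (default 100 000,
matching the modeled protocol): rotations uniform on SO(3) (normalized
quaternion sampling; the empirical mean rotation angle reproduces the
analytic 126.48° of the `(1 − cos θ)/π` density), translations at
uniformly chosen envelope voxels with sub-voxel jitter. Proposals are
screened cheaply (coverage within 0.15 of the filter, then the
closed-form correlation) and shortlisted for refinement *stratified by
space*: proposals are binned by placed-centroid cells of `stratify_cell`
(4 Å); shortlist slots are granted one per cell in descending score
order and only then topped up. Without the cap, one high-scoring density
region floods the whole shortlist and placements in weaker regions are
never refined at all — in practice the cell containing the correct
placement can rank a few hundredth among cells, so the shortlist must
cover hundreds of distinct cells rather than the best few. Shortlisted placements are then
refined by greedy coordinate descent on the correlation itself — axis
translations and centroid rotations with step halving from
1 voxel / 16° down to 0.02 Å / 0.1° — the wide initial rotation step
extends the converging basin to ~45° of rotational error, which sets
how many random proposals a reliable hit needs. Refined placements with envelope coverage below
`coverage_min` (default 0.60, matching the modeled protocol) are
discarded; survivors are de-duplicated by greedy CA-RMSD clustering at
`cluster_rmsd` (default 5 Å — the protocol reports only resulting library
sizes of 500–2800, which caps `max_candidates`), keeping each cluster's
best-correlation member. Ranking is by correlation, ties broken by
coverage then proposal order; generation is bit-reproducible for a fixed
seed. Screening before refinement is a cost choice: placements that
cannot reach the filter or score far below the field do not survive
clustering either.

## Assembly objective

One configuration assigns each subunit one library candidate; placements
stay frozen ("configurations of the fits pre-calculated"). The composite
score, lower better, is

    total = w_cc · (1 − cc)
          + w_xl · Σ_links min( (max(0, d − max_dist) / soft_scale)², xl_cap )
          + w_clash · n_clash

with `cc` the Pearson correlation of the combined simulated density
against the target map, `d` each cross-link's Cα–Cα distance taken as the
minimum over identical copies, `max_dist` = 35 Å for DSSO, `soft_scale`
= 10 Å, `clash_cutoff` = 4 Å on inter-subunit CA pairs, and defaults
`w = (10, 1, 0.1)`, `xl_cap = 1`.

Two choices here are the package's own, made after the naive form failed
on its own study conditions. First, the per-link penalty is **capped** at
`xl_cap`: cross-link tables contain false positives (the synthetic decoys
emulate them), and an uncapped quadratic lets a single hopelessly
violated link (≈10–20 score units at typical decoy distances) outweigh
the entire density term, moving the *exhaustive* optimum off the ground
truth. A bounded penalty is the standard outlier-tolerant treatment of
such restraints. Second, the density weight is 10, not 1: the density
term's dynamic range is at most 1 by construction, so it must be scaled
to the magnitude of the restraint sum for map agreement to dominate and
cross-links to act as disambiguators rather than drivers. Both constants
are configurable.

## Simulated annealing

Metropolis acceptance with geometric cooling (default factor 0.995 per
step, 10 000 steps; tests and the acceptance study use 3 000). The
initial temperature is auto-calibrated so that ~50% of 100 random trial
moves from the start configuration would be accepted (no schedule is
published for the modeled protocol). Moves: re-pick one subunit's
candidate (probability 0.7; within that, 30% of draws come from the
library's top 10 — the libraries are sorted by single-subunit fit score,
and exploiting that ranking speeds convergence), swap the candidates of
two identical copies (0.2; exercises label symmetry, which leaves the
score exactly unchanged for geometrically identical candidate sets), and
a *site exchange* (0.1): two subunits jump to the candidates nearest each
other's current centroid. The exchange move exists because the dominant
failure mode of single-subunit moves is a two-subunit exchange trap
(each sitting in the other's density) whose escape path is always
uphill. Runs are bit-reproducible for a fixed seed; equal best totals
are resolved toward lexicographically smaller candidate indices, so exact
score ties are deterministic by design. `anneal_multi` runs N independent
seeds (default 5) and keeps the lowest total — multi-start selection is
the standard guard against the remaining traps (including three-subunit
occupancy cycles that pairwise moves cannot unwind). Its first run
starts from every library's top-ranked candidate, the conventional
heuristic start; the others start randomly, and its run list feeds
the ensemble analysis, which greedily clusters per-subunit placements by
CA RMSD (default 3 Å) into modes with populations and within-mode
spreads. An exhaustive enumerator provides the exact optimum on spaces up
to 10⁶ configurations as an oracle.

## Cross-link layer

DSSO cross-links impose a 35 Å Cα–Cα upper bound. Tables are CSV with
`protein_a, residue_a, protein_b, residue_b[, linker][, max_dist]`.
Mapping onto a model resolves each protein label to one or more chains
(paralog/copy ambiguity); every copy-pair distance is reported and
satisfaction is judged on the minimum — mirroring how a link to a
two-copy protein is reported once per copy. An empty mapped set has
satisfaction 1.0 by vacuous truth, flagged by `n_mapped = 0`. Distances
are Cα–Cα only; a per-protein integer offset accommodates numbering
mismatches. Unmapped links are listed, never dropped.

## Validation layer

* **CCmask** — Pearson correlation between map and model-simulated map
  over voxels within `mask_radius` (default 3 Å) of any atom. The
  published values this models came from an external validation suite
  whose exact mask construction (atom radii, dilation) is not described,
  so agreement there is approximate by nature.
* **Density explained** — fraction of voxels at or above a threshold
  lying within `mask_radius` of any model atom. At low thresholds and
  6–10 Å resolutions the density skirt extends several Å beyond the
  atoms, so a radius of ~6 Å is the sensible companion to a low-density
  threshold; 3 Å suits tight masks.
* **Clash count** — inter-subunit CA pairs closer than 4 Å (a simple
  excluded-volume check; full all-atom clash scores are out of scope).
* **Coexpression** — Pearson R between two genes' tissue nTPM vectors
  with the two-tailed P from `F = r²(n−2)/(1−r²)` on (1, n−2) degrees of
  freedom, exactly the F test of a simple linear regression and
  algebraically identical to the two-sided slope t-test (asserted to
  1e-12 in tests, and against scipy's independent implementation).
* **Heptad registers** — all 7 phases of the `abcdefg` register are
  scored by the hydrophobic fraction at the core a/d positions
  (hydrophobic set {A,V,L,I,M,F,W,Y}; G, C, P excluded as conventional
  non-core formers) and the maximizing phase is chosen, ties to the
  lowest phase index with all maxima reported. Polar residues at a/d are
  listed as polar inclusions; proline there adds a register-breaking
  warning, not an error. Missense mutations are annotated with register,
  core membership, and charge-class change.

## Synthetic ground truth

The generator produces what the statistics assume: a rigid complex of
CA-only subunits with known placements, a simulated map at a stated
resolution, and a cross-link table with construction margins. Subunit
geometry is an ideal α-helix (rise 1.5 Å/residue, radius 2.3 Å,
100°/residue) or, by default, a self-avoiding random walk with 3.8 Å
steps and a 3.4 Å exclusion radius — the default is the walk because its
irregular shapes are identifiable at 6–10 Å, whereas a lone straight
helix is nearly degenerate under rotation about its own axis. Subunits
are placed by random rotation and a bisected approach along a random
direction until the inter-subunit CA gap sits within [min_separation,
min_separation + 3 Å]; identical-copy groups share canonical coordinates
so the two-copies scenario (including label-swap symmetry) is exercised.

True cross-links are sampled uniformly from *inter-subunit* CA pairs at
most 30 Å apart in ground truth — the 5 Å margin under the 35 Å bound
makes satisfaction robust to small placement error, and intramolecular
links are excluded by default because they carry no assembly information
(an `include_intra` switch adds them, at sequence separation ≥ 5).
Decoys — `ceil(decoy_fraction · n_true)` of them — come from pairs beyond
45 Å, an unambiguous violation band; both margins are evaluated on the
minimum-over-copies distance, so they hold even under copy ambiguity.

Default study conditions: 3 subunits × 60 residues, 8 Å map on 2 Å
voxels with 12 Å padding, 12 true links + 20% decoys, no voxel noise
(uniform additive Gaussian noise is available but off by default). What
the generator does *not* emulate: CTF and solvent effects, B-factor
heterogeneity, resolution anisotropy, side chains, and real linker
chemistry — passing tests therefore demonstrate the machinery's
correctness and the procedure's identifiability under clean conditions,
not performance on experimental maps.

## Problem sizes used in tests and the acceptance study

The recovery study runs the full pipeline at the default study
conditions with the production `n_searches = 100 000` and
`refine_top = 400` per subunit,
annealing for 3 000 steps with best-of-5 multi-start, over 10 pipeline
seeds. The search count matters: a placement is only refinable from
within ~30° and a few Å of the truth, so the joint hit probability per
random proposal is a few 10⁻⁵ and on the order of a hundred thousand
searches are needed for a reliable, *accurate* hit — that arithmetic is
the reason the 100 000-search production figure exists at all. The stratified shortlist (see above) is equally
load-bearing: without it, one strong density region floods all
refinement slots and placements in weaker regions are never refined.
These sizes were validated as the scale at which the default bundle's
fit libraries contain the true placement as their top candidate across
complex and search seeds. The annealer-vs-oracle study uses a 5×5×5 candidate space (the
truth placement plus four displaced alternatives per subunit) and 20
annealing seeds against the exhaustive 125-configuration minimum.

## Known limitations

Rigid placements only — no flexible refinement, symmetry-aware fitting,
or FFT-exhaustive translational search. Whole-grid correlation in the
assembly objective assumes the map region is dominated by the modeled
subunits. The closed-form fit score deviates from grid-space Pearson near
map edges (truncated Gaussian mass). Cross-link tables are taken as
given; no spectral-level identification or FDR modeling. Heptad scoring
uses hydrophobicity only, with no knobs-into-holes geometric check.
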