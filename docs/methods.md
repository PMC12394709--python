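# Methods

This note records the models behind each stage, the parameters that
matter, and the choices made where the underlying workflow left the
design open.

## Trace isolation

A fossil plate is modelled as a light matrix (intensity near 1) bearing
dark granular puncta (intensity near 0), modulated by a smooth
multiplicative tone field. The chain is:

1. **Tone balancing.** A polynomial field (default order 1) is fitted by
   least squares to the background and divided out. Background selection
   is two-pass: the first pass takes pixels above the median intensity
   (traces are dark and sparse), the second refits on every pixel whose
   ratio to the first fit exceeds 0.5. The second pass matters: a one-pass
   median cut truncates the background sample by value and tilts the
   fitted field. Constant plates are passed through with a warning.
2. **Dark threshold.** Blackness is K = 1 − intensity, the K channel of a
   neutral-gray CMYK decomposition (for grays, C = M = Y = 0, so K is
   exactly blackness). The mask keeps K ≥ `k_frac`; default 0.87.
3. **Inversion** to white profiles on black.
4. **Gaussian density.** Normalised isotropic Gaussian, reflective
   boundaries (no edge darkening on cropped plates), kernel truncated at
   6σ so the discarded tail is below 1e−8 and punctum mass is conserved
   to better than 1e−6. The workflow this emulates specifies a blur
   "radius" R = 10 px in an image editor whose radius-to-σ mapping is
   proprietary; σ is therefore declared directly, default 10 px, and
   recorded in provenance. The blur is qualitative (puncta must run
   together), so nothing downstream depends on the exact mapping.

Color input is collapsed to grayscale by BT.709 luminance.

## Symmetry reconstruction

Assumption: the organism is bilaterian, so left and right neural traces
are samples of one mirror-symmetric organ exposed at two taphonomic
depths. The reconstruction maximises over the two halves rather than
averaging them — traces are evidence of presence, absence is erasure, so
union (per-pixel max) is the right combination; averaging would halve the
signal wherever only one depth preserved it. Additive blending is
available for the opacity-stacking workflow.

Registration is landmark-based and deterministic: closed outlines are
resampled to 64 points by arc length from the user-marked start vertex
with orientation normalised to positive shoelace area (reflection
reverses vertex order; the renormalisation restores point-for-point
correspondence). The annotated start vertex should sit on or near the
midline so that the reflected outline corresponds to itself; the
synthetic annotations place it at the topmost foramen point. Rigid
(rotation + translation) least squares is used within a specimen — the
two halves of one fossil share a scale — while cross-specimen compositing
allows uniform scale (similarity transform), since specimens differ in
size. The degenerate failure mode (all landmarks coincident) raises; the
estimator is scikit-image's Umeyama least squares.

The final map is built by duplicating the merged reference half across
the axis, which makes reflection-invariance exact by construction for a
grid-aligned midline and within bilinear-resampling tolerance otherwise;
the invariant is asserted (max |map − reflect(map)| ≤ 2/255 after a 1-px
dilation allowance) on every `symmetrize` call.

The midline is taken from annotation, not auto-detected: placing the
antero-posterior axis is anatomical knowledge. (A reflective-correlation
axis search was considered and rejected as out of scope for the core
pipeline.)

## Cone-cell (Semper cell) counting

Peaks are defined chromatically: within an ommatidium ROI, pixels whose
hue lies in a configured band (default 70°–150°, the yellow-green
fluorescence band; the source workflow does not give the band
numerically, so it is an explicit config value reported with every
result), saturation ≥ 0.3, and HSV *value* above the q = 0.95 quantile of
the in-band values. Value (not per-channel maxima) is used as the
intensity axis; the quantile is computed after smoothing the value
channel with a σ = 1.5 px Gaussian so that "peaks" are local intensity
maxima rather than single noisy pixels (set `value_smooth=0` to disable).
Units are 8-connected components with area ≥ 3 px (both configurable);
counts above four, or units touching the ROI boundary, are flagged
ambiguous rather than interpreted — the biological reading of such
counts is explicitly uncertain.

## Synthetic data

The generator emulates the features of compressed fossil plates that the
pipeline must survive, with exactly known ground truth:

- **Template**: paired eyestalk neuropils with an optic-lobe chain,
  circumesophageal cords, ocellar nerves, and a medial synganglion ring
  around the esophageal foramen, placed on the right of a vertical
  midline and mirrored, so region-set symmetry is exact by construction
  (the midline sits between pixel columns; reflection is an integer
  column map). Default plate 360 × 440 px, regions ≈ 20 % of the plate.
- **Puncta**: mirror pairs sampled uniformly in the region union at
  `punctum_density` (default 0.02 px⁻²) and rendered as disks of radius
  2 px at intensity 0.05 on background 0.92 — safely astride the 87 %
  blackness threshold. The density default puts the blurred in-region
  plateau at roughly three times the practical foreground level even
  after half-strength erasure, giving contrast headroom without merging
  separate regions.
- **Axial rotation**: each mirror pair carries a latent depth
  u ~ U(0,1); at rotation asymmetry r the left copy is erased when
  u < r/2 and the right when u > 1 − r/2. Erased sets are disjoint; at
  r = 1 the sides survive on complementary depth ranges, at r = 0
  nothing is erased. This is a stand-in: the real phenomenon (two
  exposure depths from rotation during compaction) has no published
  quantitative forward model, so recovery results on synthetic plates
  bound what the pipeline can do under *this* erasure model, not under
  real taphonomy.
- **Speckle** (Poisson background puncta), **tone gradient** (random
  first/second-order multiplicative field), and per-region rigid
  **lateral shifts** complete the degradations. Mineral chemistry,
  fracture texture and photographic artifacts are not modelled; passing
  the recovery tests shows robustness to the modelled degradations only.
- **Character matrices** are evolved on known trees under the symmetric
  2-state Mk process with stationary root states. Rate convention: total
  leaving rate 1 per unit branch length, so P(change|t) = (1 − e^(−2t))/2.
  Missing entries are masked uniformly at rate `missing_frac`.

Recovery is scored by Dice overlap between the template mask and the
foreground of the density map extracted by Otsu's threshold — the
natural cut for the bimodal plateau/background histogram, and one that
measures region recovery rather than the width of the blur halo. The
fixed-level foreground {density > 0.05} is used where the comparison
target is the halo-dilated mask.

## Parsimony engine

Characters are packed two bits each into Python integers (one "contains
state 0" word, one "contains state 1" word per node), so a Fitch pass
costs ~10 integer operations per internal node for any character count up
to the word width; `?` is the full state set at a leaf. Weighted lengths
group characters by distinct weight (non-integer weights are fixed-point
scaled by 10⁶, which also makes reweighted searches exactly
reproducible).

The heuristic search is the classic protocol: each replicate draws a
random taxon-addition order, builds a starting tree by best-insertion
stepwise addition, and hill-climbs with first-improvement TBR (every
bisection, every reconnection pair, randomised scan order). All distinct
topologies at the overall best length are kept, and the set is closed
under equal-length TBR moves (capped at `max_trees`, default 100, with
the truncation logged) so that complete tree islands — and hence honest
MPT counts and strict consensus — are reported. Determinism: one seeded
generator drives the whole search; identical seeds give identical
results. A 26-taxon × 120-character search at 100 replicates takes on
the order of two minutes on one core; the published protocol's 1,000
replicates are a config value away when wall-clock allows.

Fit indices follow the standard definitions; because published CI/RI
values do not always state whether parsimony-uninformative characters
were included, both conventions are computed and reported. RC is defined
as 1 for uninformative characters (g = m) and for constant ones, which
keeps them at full weight during successive reweighting — the common
software convention. Reweighting uses the best-fit (maximum over MPTs)
RC by default, mean-RC optionally; rounds are counted as weight
assignments, so a homoplasy-free matrix stabilises after one round.

The bootstrap resamples characters with replacement (respecting existing
weights — a resample is represented as integer multiplicity weights, so
the fast weighted scorer applies), reruns a reduced search per replicate
(default 2 addition replicates), and tallies the splits of each
replicate's strict consensus.

## Mk / Mkv likelihood

Felsenstein pruning, vectorised over characters, with the closed-form
2-state transition matrix. Missing tips contribute flat partials. The
Mkv correction divides every character's likelihood by
1 − L(constant): the summed likelihood of the two fully observed
constant patterns on the same tree, the standard conditioning for
matrices in which constant characters are never scored (characters with
missing data use the same correction). By reversibility the score is
independent of the pruning root, which is asserted in tests. Branch
lengths can be coarsely optimised by bounded scalar search per branch
(a scorer for fixed topologies, not a tree search); likelihood tree
search and Bayesian MCMC are out of scope.

## Problem sizes used in the checks

The shipped verification runs use: 100 random-addition replicates on the
full-size (26 × 120) synthetic stand-in matrix; 50 seven-taxon matrices
against exhaustive enumeration (945 topologies each); 50 five-taxon
likelihood cases against internal-state enumeration; 20 simulation seeds
for 12-taxon topology recovery at 500 characters and branch length 0.1;
200 bootstrap replicates; 50 cone-fixture seeds. These sizes were chosen
so the whole battery completes in minutes on a single core while keeping
every estimate's sampling error far from its acceptance margin.

## Known limitations

- The published character matrix itself ships as a journal supplement
  and is not redistributed here; full-size cladistics checks therefore
  run on the synthetic stand-in above, which matches its dimensions and
  missing-data fraction but not its signal structure.
- The erasure model for axial rotation is a stand-in (see above).
- Only binary characters are supported (the matrices this targets are
  binary by construction); no ordered/multistate characters, no model
  selection, no posterior probabilities.
- Registration is rigid/similarity only; nonrigid deformation of
  compressed fossils is not corrected.
- The half-isolation boundary is the annotated midline; an anatomical
  crop (e.g. beneath the ipsilateral eyestalk) can be imposed through
  the ROI landmarks but is not inferred.
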