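# Methods

## The maturation model

In *C. elegans* oogenesis, crossover interference operates over whole
chromosomes, so each of the six homolog pairs normally receives exactly
one crossover-designated site (visible as a COSA-1 focus in late
pachytene).  A site that matures into a crossover produces a chiasma,
which holds the two homologs together as one bivalent through
diakinesis.  Counting separable DAPI-stained bodies therefore reads out
chiasma success: a nucleus with *d* bodies carries 12 − *d* chiasmata
(6 bodies = all bivalents, 12 = all univalents).

When maturation is unreliable, the chiasma distribution is a *binomial
thinning* of the focus-count distribution.  Assuming every focus
matures independently with the same probability *p*, a nucleus with *m*
foci lands in chiasma class *k* with probability C(*m*, *k*)
*p*ᵏ(1 − *p*)^(m−k), so the expected adjusted class weights are

    N′_k = Σ_{m ≥ k} N_m · C(m, k) · p^k · (1 − p)^(m − k)

`adjust_distribution` implements this map exactly (each binomial row
sums to one, so total weight is conserved; the thinning mean law
E[k′] = p·E[k] follows and is property-tested at 1e-9 tolerance).

### Preprocessing

Focus counts of 7 or 8 — double-labelled or touching signals — are
clamped onto 6 before fitting (`clamp_counts`), since the model allows
at most one designated site per pair.  Because focus and DAPI-body
samples typically come from different numbers of nuclei, the focus
distribution is rescaled to the DAPI total (`normalize_total`);
fractional nucleus weights are carried exactly, with no rounding before
the objective is evaluated.  Clamping precedes normalization.

### Estimation

`estimate_p_success` minimizes SSD(*p*) = Σ_k (chiasma_k −
N′_k(*p*))² over the grid {0, 0.01, …, 1}.  Exhaustive grid search is
exact at the resolution at which success rates are reported (whole
percent), trivially reproducible, and immune to local minima; ties are
broken toward the smaller probability.  The SSD is computed on weights
(counts), not proportions — with the focus distribution pre-normalized
to the chiasma total the two differ only by a constant factor — and
always over the full support 0..6 inclusive, including classes observed
in neither input.  No confidence interval is attached: the point
estimate is the method's output, and inter-nucleus heterogeneity in *p*
is deliberately not modelled.

## The synthetic-data generator

The generator produces the data structures the analysis consumes, with
ground truth recorded on every nucleus.

* **Designation and maturation** (`simulate_cosa_and_dapi`): each of 6
  chromosome pairs independently receives one designated focus with
  probability `p_designate` (at most one per pair — complete
  interference); each focus matures with probability `p_success`;
  scored DAPI bodies are 12 − matured.  The designation model is the
  simplest interference-respecting generator; nothing finer is implied
  by the analysis, which conditions on the focus counts.
* **Merging artifact**: touching diakinesis chromosomes can be scored
  as one body.  Modelled as disjoint random pairs of bodies each
  collapsing with probability `p_merge` (default 0; chains of three or
  more touching chromosomes are not modelled).  With `p_merge = 0`,
  inverting 12 − DAPI recovers the true matured count for every
  nucleus, a tested invariant.
* **Pairing gonads** (`simulate_pairing_gonad`): nuclei are placed
  uniformly on a unit axis; the zone of each nucleus (equal-width bins,
  one per entry of `pairing_curve`) sets its pairing probability.
  Paired nuclei carry two locus signals 0.05–0.2 µm apart or a single
  fused signal (30% of paired nuclei); unpaired nuclei carry signals
  1.5–3 µm apart.  The defaults bracket the 0.75 µm calling threshold
  comfortably on both sides, so threshold sensitivity is not what these
  fixtures test.
* **Image rendering** (`render_image_stack`): nuclei (radius 1.5 µm)
  are laid out on a jittered grid and rendered as filled ellipsoids in
  a DAPI-like channel; each nucleus receives a Poisson(5) number of
  foci rendered as anisotropic 3D Gaussians (σ_xy = 130 nm, σ_z =
  300 nm, amplitude 150 photons) over a Poisson background of 5
  counts/voxel — amplitude-to-noise well above 5.  Voxels are
  (125, 100, 100) nm ZYX.  Foci within a nucleus are placed at least
  0.7 µm apart (the axial FWHM of the rendered PSF): they model
  distinct chromosomal sites, which are optically resolvable; two
  sites closer than the PSF would render as one blob and no detector
  could, or should, split them.  The renderer lays out its own nucleus
  field and returns truth tables directly rather than consuming a
  pairing-gonad object, because nucleus 3D geometry exists only at
  render time.

The generator does **not** emulate: structured-illumination
reconstruction artifacts, chromatic shift, intensity gradients along
the gonad, nuclear crowding/contact, or spot brightness variation.
Passing round-trip tests therefore demonstrate correctness of the
quantitation machinery under the model's own assumptions, not
robustness to every real-microscope pathology.

All randomness flows through a single `numpy.random.Generator` seeded
from `SimulationConfig.seed`; identical configurations reproduce
identical gonads bit for bit.

## Pairing quantitation

The distal gonad is divided into 5 equal-length zones (half-open
intervals, last zone closed, so position 1.0 is scoreable).  A locus is
paired when its signals are fused into one spot or separated by at most
0.75 µm in 3D — the conventional distance for germline FISH scoring,
exposed as a parameter since it is a convention, not a measurement.
Fused and sub-threshold two-spot signals are treated identically; a
locus with no signal is excluded from the denominator and logged.

The gonad is the replicate unit: each gonad contributes one fraction
per zone, and the cross-gonad mean and sample SD (ddof = 1) are
reported, matching how gonad-count-based error bars are constructed.
Genotypes are compared per zone with two-tailed two-sample t tests on
the per-gonad fractions.  Zones where both sides have zero variance get
p = 1 (equal means) or 0 (unequal) by convention; zones with fewer than
two gonads on either side are undefined (NaN).

## Focus counting

Segmentation: Otsu threshold (overridable) → 3D connected components →
filter by physical volume (defaults 2–50 µm³ for ~3 µm germline
nuclei).  Out-of-range components are removed from the labels and
reported in a `flagged` list — the "semi-automated" part: flagged
nuclei are meant for manual review, and an override table
(nucleus → corrected count) can replace automatic counts before zone
summaries.

Detection: the signal channel is filtered with a scale-normalized
negative Laplacian of Gaussian at the rendered PSF scale (σ defaults
(0.3, 0.13, 0.13) µm ZYX); local maxima above an absolute response
threshold (default 5.0) and separated by ≥ 0.25 µm become candidates.
A candidate is kept only if it lies inside the 3D convex hull of a
nucleus's voxel cloud (Qhull; degenerate flat clouds fall back to a 2D
hull plus a one-slice z tolerance) and is assigned to that nucleus.
All parameters are echoed in `params_used` for provenance.

Zone counts use 7 equal-length zones by default; per-zone summaries
report n, mean and quartiles (box-plot convention), and conditions are
compared with the two-sided Mann-Whitney rank-sum test — exact null
distribution when both samples have ≤ 25 observations, tie-corrected
normal approximation above that (the regime of real data, with
hundreds of nuclei per zone).

## Interference contingency test

`double_focus_test` builds the 2×2 table (double-focus vs other nuclei,
condition A vs B) and computes the two-sided Fisher exact p by
enumerating all tables with the observed margins and summing the
hypergeometric point probabilities of every table no more probable than
the observed one (point-probability convention, with a 1e-7 relative
guard so the observed table is never excluded by float noise).  Tests
cross-check it against `scipy.stats.fisher_exact` and a from-scratch
`math.comb` enumeration.

## Progression extents

Nuclei are grouped into consecutive axial columns (default width 0.07
normalized units ≈ two nucleus diameters for a ~100 µm distal gonad —
a convention, exposed as a parameter).  A column is marker-positive on
a strict majority (ties negative); empty columns inherit the previous
column's state.  The measured span runs from the first positive column
to the end of the first contiguous positive run, divided by the
distance from that start to cellularization, ×100.  Marker
reappearance after the measured span (seen for some phospho-markers in
aged germlines) is recorded in `later_runs` and logged, never silently
merged into the span.  Refining the column width moves the fraction by
at most one original column width of axial distance, a tested property.

## Numerical and scale choices

* Grid step 0.01 for the SSD search; at 1,360 nuclei the SSD curve is
  steep enough that recovery from noiseless forward maps is exact at
  grid resolution for every grid value (tested over the whole grid).
* Estimator recovery under sampling noise uses 100 replicates of 1,360
  nuclei per generating probability; mean absolute error is ~0.005,
  well inside the 0.05 reporting band.
* The rendered validation field uses 50 nuclei with ~5 foci each
  (≈ 250 spots, ~3 s to render and analyze), which gives recall and
  precision estimates with ~1.5% binomial SE — adequate to verify the
  ≥ 95% operating point.
* Physical coordinates use the voxel-center convention
  (index + ½) × voxel size, 0-based ZYX throughout.

## Known limitations

* The merging artifact is pairwise-only and defaults off; the chiasma
  inference 12 − DAPI assumes no fragmentation (counts > 12 are
  rejected) and no de-merging correction is attempted.
* The detector is tuned for the rendered PSF; real stacks need their
  own sigma/threshold settings, which is why every parameter is in the
  call signature and echoed in provenance.
* The hull constraint uses voxel clouds from segmentation; with badly
  under-segmented nuclei (fused volumes) foci are assigned to the fused
  label, exactly as a manual scorer would have to resolve them — hence
  the flagged list.
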