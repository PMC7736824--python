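# Methods

This note records the models, conventions and numerical choices behind
`replidyn`, and what the synthetic-data experiments do and do not show.

## Combing model and track grammar

Fibers are stretched DNA molecules at a constant factor of 2 kb/μm, so a
length `L` μm converts to `2L` kb.  Cells are labeled with two consecutive
pulses (IdU then CldU, 15 min each by default); a progressing fork
therefore reads IdU→CldU in its direction of travel, and fork speed is the
second-pulse (CldU) track length × stretching factor / pulse duration.
Only second-pulse lengths enter the speed statistic: the first pulse's
start is not synchronized with fork passage, so IdU lengths underestimate
synthesis.

Pattern grammar on the ordered segment list of a fiber:

- `CldU–IdU–IdU–CldU` (all abutting): a bidirectional origin, position at
  the IdU–IdU junction; each half is one fork.
- `CldU–IdU–CldU` with one merged IdU segment is accepted as the same
  origin, splitting the IdU at its midpoint.
- `CldU–IdU–IdU` / `IdU–IdU–CldU`: an origin one of whose forks lost its
  CldU to a termination (fork-merger) event; the origin is still called,
  the damaged fork is excluded from speed.  Without this rule, origins at
  short spacings are selectively dropped and the IOD mean inflates by ~2%.
- A lone `IdU–CldU` (either orientation) is a unidirectional origin only
  when its IdU edge faces unlabeled ssDNA with no other labeled track
  within an exclusion distance (default 5 μm); otherwise it is scored
  ambiguous, since a broken partner fork cannot be ruled out.

A fork enters the speed statistic only when ssDNA is visible beyond both
outer ends of its structure.  This is the bench selection rule (it guards
against broken fibers); in the simulator it also excludes forks whose
tracks merged with a converging neighbor, whose lengths no longer reflect
synthesis time.

The unidirectional percentage counts *structures*: unidirectional
structures / (unidirectional + bidirectional structures) × 100, a
bidirectional origin counting once.  Under a symmetric per-fork stall
model where each fork of an origin independently produces no track with
probability q, the expected percentage among visible structures is
2q(1−q)/(1−q²) = 2q/(1+q); q = 0.0684 gives 12.8%.

Inter-origin distances are measured between origin midpoints (the IdU–IdU
junction), matching the midpoint convention of the genome-wide zone
analysis.  Fork asymmetry is the long/short CldU ratio of a bidirectional
origin's two valid forks; pairs with a zero-length short track are
excluded and counted rather than imputed.

## Fiber simulator

Origins fire at the start of pulse 1, spaced by a truncated-normal
distribution along each fiber; each fork independently stalls with
probability `p_fork_stall`, otherwise elongates at a truncated-normal
speed through both pulses.  Converging forks from adjacent origins
terminate where their tracks would overlap (both truncated at the midpoint
of the overlap), which preserves origin midpoints — the property the IOD
recovery relies on — while making track lengths at short spacings
realistically unreadable.  Truncated-normal sampling is by rejection;
configurations whose rejection mass would exceed 50% are refused rather
than silently biased (with the positivity constraints on means this guard
is a backstop, not a working path).  Defaults (speed 1.67 ± 0.27 kb/min,
spacing 90 ± 16 kb, 15-min pulses, 2 kb/μm) reproduce the measured mES
population means; the track-length spread (2 μm sd) is the generator's
choice of a realistic dispersion, stated here because no measured value
fixes it.

What passing recovery tests shows: the estimators are unbiased under the
generator's assumptions (synchronous firing, normal speeds, no label
noise, perfect segmentation of tracks into segments).  They do not show
robustness to antibody gaps, fiber breakage mid-track, or asynchronous
firing, none of which the generator emulates.

## Origin-map interval analysis

Coordinates are 0-based half-open (BED) throughout; declared 1-based input
is converted on read.  "Reproducibly found in at least two replicates" is
implemented as per-base support counting: each replicate's peaks are first
self-merged, a boundary sweep counts distinct replicates covering each
base, and maximal runs with support ≥ `min_support` are emitted.  A
peak-overlap-count alternative (`method="peakwise"`) is provided.  Both
the sweep and the clustering are verified against naive per-base /
quadratic-linkage oracles on random instances.

Initiation-zone clustering is single-linkage on edge-to-edge gaps
(≤ 22 kb by default, the mapping resolution of Okazaki-fragment origin
sequencing); midpoint linkage would split wide adjacent peaks that
physically touch.  Zone IODs are midpoint-to-midpoint between adjacent
zones per chromosome; a distance is omitted (and counted) when it crosses
a declared unmappable gap, or — with no gap track — when it exceeds a
1 Mb ceiling, a stand-in criterion chosen because unmapped-region lists
are not always available.

## Imaging

Stacks are rescaled to isotropic voxels (linear interpolation in z) before
quantification; intensities are divided by the voxel-count factor so the
integrated intensity is conserved, keeping sums comparable across
resolutions.  Nucleus segmentation is Li-threshold on a 0.04-μm-smoothed
DAPI channel (Li is stable when background dominates the volume), holes
filled, objects under 2 μm³ removed, with optional marker-controlled
watershed on the distance transform to split touching nuclei.  Interactive
pixel classification used in the original imaging workflows is replaced
throughout by these deterministic thresholds; the downstream filters are
kept verbatim:

- confocal: smoothed-Otsu threshold, EDT-watershed separation, objects
  < 200 voxels (≈ one confocal PSF) discarded, objects kept only when
  > 50% of their volume overlaps the nuclear mask;
- 3D-SIM: triangle threshold, touching-object separation, objects
  < 0.0002 μm³ discarded, centroid required inside a nucleus;
- pseudo-widefield: −2 px x/y registration shift, per-slice rolling-ball
  (radius 10 px) background subtraction, Otsu threshold, objects
  < 0.02 μm³ discarded.

Solidity is voxel count over convex-hull voxel count (1 by convention when
a hull is undefined); border distance is the Euclidean distance transform
of the nucleus at the focus centroid; chromocenter "compaction" is defined
here as mean DAPI inside the object over mean DAPI in the surrounding
nucleoplasm, and "shape factor" as sphericity π^(1/3)(6V)^(2/3)/A with the
surface area from a marching-cubes mesh — both fixed as package
conventions since no standard definition exists.  Nanofoci are assigned to
the pseudo-widefield focus containing their centroid, boundary cases to
the focus with the larger overlap; unassigned nanofoci are reported, and
the clustered mean averages counts over pWF foci holding ≥ 2 nanofoci.  A
true pWF optical channel can be supplied; otherwise a surrogate is
synthesized by blurring the SIM channel to 250 nm lateral FWHM, which
reproduces the qualitative clustering but not the optical transfer
function of a real widefield system.

The stack simulator draws cluster sizes from a named law (default for the
clustering analyses: 1 + Poisson(2.845), whose mean over sizes ≥ 2 is
1 + λ/(1 − e^(−λ)) ≈ 4.02), scatters members within a pWF-scale radius,
renders foci as 3D Gaussians inside oblate (coverslip-flattened) nuclei
with DAPI texture and chromocenter blobs, and adds Poisson + Gaussian
noise.  It does not model a microscope PSF, reconstruction artifacts or
depth-dependent aberrations, so segmentation-recovery results speak to the
thresholding/filter logic, not to optics.

## Replicon arithmetic and kinetics

All derived quantities are kept at full precision and rounded only for
presentation: half-up to integers for counts and hours, two decimals for
the replicons-per-focus ratio, nearest hundred for total origins.  The
single-fork percentage uses the unrounded ratio.  Genome-size ranges
propagate endpoint-wise (valid because every formula is monotone in GS);
the single-fork percentage is antitone, so its pair is reported in
genome-size order rather than sorted.  With GS = 6.5 Gnt and IOD = 90 kb,
GS/IOD = 72,222 rounds to 72,200 at the nearest hundred; a printed source
value of 72,300 for this quantity is not reproducible under any rounding
of the stated inputs and is treated as a typographical inconsistency.

Doubling time averages per-timepoint estimates of t/log2(n_t/n_0) against
the first measurement; non-increasing counts yield a flagged negative (or
infinite) value rather than an error.  Stage durations are doubling time ×
stage cell fraction, so they conserve the doubling time by construction.

## Problem sizes

The test suite and the acceptance analysis run on deliberately moderate
problem sizes chosen to give stable statistics: ≥ 5,000 forks for speed
recovery, ≥ 2,000 origin pairs for IOD recovery, ≥ 20,000 origins for the
stall model (3×SEM acceptance bands in each case), 300 ground-truth foci
on a 28×320×320 stack for segmentation recovery, and 10⁵ draws for the
cluster-size law.  Each quantity is recovered under the fiber regime in
which its structures are readable: sparse origins for fork speed (no
termination events), dense origins for IOD.

## Known limitations

- The combing classifier assumes noise-free segment tables; it has no
  tolerance parameter for staining gaps within a track.
- Deeply merged origin structures (both CldU tracks fully consumed) are
  genuinely ambiguous on the fiber and are dropped; at 90-kb spacing with
  30-min labeling this leaves a small upward IOD bias (≈0.5%).
- The rule-based S-phase stage helper is a convenience, not a validated
  classifier; stage labels are expected as input.
- The pseudo-widefield surrogate and the absence of PSF simulation mean
  absolute pWF focus counts are not comparable to real widefield data.
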