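# Methods

## The locus model

The reference is *collapsed*: all physical rDNA repeats map onto a
two-repeat interval, mirroring how reads from a tandem array align to a
standard yeast assembly. Copy number therefore manifests only as read
depth over the collapsed interval. The default model has

* one unique chromosome (`chrU`, 11.65 Mb) plus an array chromosome
  (`chrXII`) with a 450 kb unique flank followed by the 2 × 9,100 bp
  collapsed array, so the array occupies coordinates 450,000–468,200
  and total unique (non-rDNA) sequence is 12.1 Mb — chosen so a
  150-copy array contributes ~10% of genomic DNA, the typical
  wild-type share;
* within-repeat offsets (bp from repeat start): ACS 2000, nondisplaced
  MCM site 1850, displaced site 2000 (150 bp displacement, the distance
  C-pro transcription pushes a loaded double-hexamer), C-pro start 1800
  (~200 bp from the rARS), RFB 3350 (1.5 kb from the loading site),
  nucleosome dyads +1/+2/+3 at 1760/2165/2330 (the +1 abuts the
  loading site; +2/+3 phased 165 bp apart right of the displaced
  site). Experimental footprinting constrains the *distances* between
  these features, not their absolute positions in the repeat, so all offsets
  are configurable; analyses read them from the model, never hard-code
  them.
* an origin catalog of 111 early + 101 late origins interleaved on the
  unique chromosome, plus the rDNA origin. 25 of the early origins are
  tagged `weak_early` — the subset whose firing is suppressed when the
  rDNA fires early. "Early" selections include them throughout (111 =
  86 + 25).

Coordinates are 0-based half-open internally. Fragments are reduced to
their midpoint, `floor((start+end)/2)`; a fragment belongs to a window
iff its midpoint lies in the half-open window. This single convention
is used by every quantification.

## The synthetic-data generator

Each assay is an explicit finite mixture over genomic components;
`n_fragments` fragments are drawn multinomially from the mixture
weights rather than by simulating cells and repeats individually —
equivalent in distribution and far cheaper. One integer seed feeds an
independent substream per assay, so libraries are byte-reproducible.

**S-seq.** G1 midpoints are sampled proportionally to local copy number
(collapsed-array base pairs weighted N/2); S-phase midpoints carry the
extra factor (1 + f) from a per-bin replicated-fraction track f.
Fragment lengths model sonication (uniform 150–450 bp). The default
track is a seeded permutation of an even grid on [0, 1] over unique
bins, so the genome median is exactly 0.5 by construction, with the
rDNA bins set to the scenario's value (0.35 for the wild-type-like
condition, 0.815 for the *sir2*-like one — the values whose expected
Trel equals the 0.90 and 1.21 timing anchors).

**MCM2-ChEC time course.** Licensed repeats (fraction L = 0.75) carry a
double-hexamer at the displaced site with probability p_d, else at the
loading site. Footprint fragments are ~N(65, 4) bp clipped to 51–100
with 3 bp midpoint jitter; nucleosome-adjacent fragments (~N(165, 10)
clipped to 151–200) are emitted with probability occ_k only where the
co-located MCM is present (+1 with the nondisplaced, +2/+3 with the
displaced helicase). After release into hydroxyurea, footprints decay
exponentially (nondisplaced λ_n = 0.002/min, displaced λ_d = 0.02/min
by default — the anchoring observation is monotone signal loss with
near-complete displaced loss by 90 min; an exponential with constant
rate is the minimal kinetic law consistent with it, and 200 mM HU slows
forks ~20-fold, motivating the 50 bp/min fork speed). Signal lost from
the rDNA MCM sites is redeposited uniformly on the 300 bp immediately
left of the RFB; nucleosome and genomic-origin losses are redeposited
into the uniform background. The grand mixture weight is therefore
constant in time — fragments move, none vanish — so with equal library
sizes the max-total scale factors are ~1 and retained fractions
estimate the survival functions directly. Genomic origin footprints
decay at 0.02/min (early) or 0.0005/min (late).

**MNase-seq.** The three modeled dyads emit nucleosomal fragments with
probabilities (occ₁, occ₂, occ₃) = (0.9, 0.25, 0.35) scaled by copy
number; the unique genome carries a phased background nucleosome every
165 bp. Inside the collapsed array only the modeled dyads emit, so
dyad-window occupancy ratios are background-free. (Real rDNA chromatin
has many more nucleosomes; only the origin-proximal three matter for
the +1-normalized statistic.)

**EdU-seq.** Every origin draws `cells_per_origin = 200` exponential
firing times at its class rate (the rDNA repeat draws the
displaced/nondisplaced rate mixture and contributes N·L repeats of
signal); a cell that fired at T contributes reads uniform over
± fork_speed·(harvest − T). Averaging over cell draws mimics a
sequenced population: per-origin signal concentrates near its
expectation while preserving the sampling law.

**Licensing Southern.** Target band expectation
baseline·(1 − L·cut_efficiency), constant loading control, uncut band
proportional to copy number, all with multiplicative lognormal noise
(σ = 0.05).

### Genotype parameter table

| parameter | wt | sir2 | fun30 | fun30 sir2 |
|---|---|---|---|---|
| displaced fraction p_d | 0.10 | 0.70 | 0.20 | 0.80 |
| displaced rate λ_d (/min) | 0.02 | 0.02 | 0.005 | 0.005 |
| occ₂ / occ₃ | 0.25/0.35 | 0.25/0.35 | 0.50/0.70 | 0.50/0.70 |
| weak-early rate scale | 1.0 | 0.5 | 1.0 | 0.75 |
| C-pro level (per copy) | 1 | 20 | 2 | 40 |
| physical copies | 150 | 150 | 150 | 52 |

All values encode the measured qualitative effects: Sir2 loss
de-represses C-pro (displacement, early rDNA firing, weak-early origin
suppression); Fun30 loss raises +2/+3 nucleosome occupancy ~2×, slows
displaced firing ~4× and adds a little displacement; the double mutant
carries a contracted array (~0.35× wild type). The wild-type displaced
fraction (0.10) is a placeholder for a small minority, and the
absolute HU firing rates are anchored only by their orderings and the
near-complete 90 min displaced loss. `weak_early_scale` multiplies the
*firing rate* of the weak-early subset in both the ChEC-decay and EdU
simulators; its value tracks the rDNA's early-firing burden (fully
suppressed in *sir2*, mostly relieved when *fun30* slows displaced
firing), which is what lets the weak-early activity ordering
WT > *fun30 sir2* > *sir2* emerge from the generator.

## Analysis conventions

* **Trel**: per-bin total-scaled S/G1 ratio divided by its genome-wide
  median; median (not mean) so the heavy rDNA bins cannot drag the
  normalizer. Default 1 kb bins; bins with fewer than 20 G1 counts are
  undefined. Region values are unweighted means over bins fully inside
  the interval. No smoothing by default (an optional moving median of 5
  bins exists for display only).
* **Depth normalization**: all multi-library comparisons use the
  max-total rule (factor_i = max_j total_j / total_i), the standard
  normalization for EdU data, adopted uniformly for the ChEC time
  course for want of a better-motivated alternative.
* **Size classes**: MCM footprints 51–100 bp (the protection is ~65 bp),
  nucleosomes 151–200 bp (the conventional nucleosomal range).
* **rDNA windows**: the displaced/nondisplaced decay windows default to
  100 bp so the two windows, 150 bp apart, stay disjoint; genomic
  origins use 200 bp windows; EdU uses 5 kb windows. rDNA
  profiles are folded onto one repeat (both collapsed copies summed by
  within-repeat offset) to double signal.
* **Peak calling**: Gaussian smoothing (default bandwidth 10 bp), local
  maxima accepted greedily in decreasing height with a 100 bp minimum
  separation, ties to the leftmost coordinate, candidates below 5% of
  the maximum discarded. These defaults always resolve two equal peaks
  150 bp apart and are invariant to uniform scaling of the profile.
* **Rate fits**: ln R regressed through the origin (R(0) = 1 enforced),
  closed form λ = −Σ t ln R / Σ t²; timepoints with R = 0 are dropped
  with a warning. Windows with fewer than 50 G1 counts are flagged
  unreliable, not silently dropped.
* **t tests**: "Student's t" is the pooled-variance two-sample
  two-tailed test (Welch available via `equal_var=False`); EdU genotype
  comparisons use unpaired t on per-origin drop vectors (a paired
  variant is available), with zero-signal origins excluded pairwise.
* **Licensing**: `cut_efficiency` defaults to 1 (raw depletion is the
  licensing estimate); estimates outside [0, 1] are clipped and
  flagged, never silently. qPCR assumes efficiency 2.0 and exactly
  two-point log-linear calibration.

## Problem sizes

The test suite and the acceptance script run entirely on simulated
data: 2 × 10⁶ fragments per S-seq library (G1 read-share SE ≈ 0.02 pp;
copy-number SE ≈ 0.3 copies), 2 × 10⁵ fragments per ChEC library
(thousands of counts per rDNA MCM window, hundreds per genomic origin
window), 10 replicate seeds for rate-recovery and licensing checks.
These sizes make counting error a small fraction of every stated
tolerance while keeping the full suite under a minute of simulation
time.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: depth
proportional to copy number and replication state, footprint/nucleosome
size separation, conditional nucleosome emission, first-order firing
with redistribution to the RFB, and genotype effect directions. It does
**not** simulate sequences, read errors, PCR duplicates, mappability,
cell-cycle asynchrony beyond the G1/HU design, fork collisions,
checkpoint signaling, or repeat-to-repeat heterogeneity beyond the
licensed/displaced dichotomy. Passing tests therefore demonstrate that
the estimators recover the generative parameters under the declared
model — not that the model captures every property of real libraries.
Real-data quantities that depend on unmodeled features (absolute read
depths, mappability artifacts at repeat junctions) are out of scope.

## Known limitations

* The exponential firing law and its absolute rates are a modeling
  choice; only rate orderings and endpoint retention are anchored.
* The collapsed-repeat fold assumes both collapsed copies are
  statistically identical; junction effects are ignored.
* `copies_from_fraction` inherits any bias in the unique-length
  constant U; it reports relative changes more faithfully than absolute
  copies.
* The licensing estimate conflates incomplete cutting with incomplete
  licensing unless `cut_efficiency` is supplied.
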