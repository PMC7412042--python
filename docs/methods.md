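# Methods

This note records the models implemented in `pecg_ira`, the parameter
choices that matter, the conventions adopted where the underlying
methods leave freedom, and what the synthetic validation does and does
not demonstrate.

## Synthetic cohort generator

The generator (`pecg_ira.synthetic`) models the cardiac electrical
dipole as a train of beats, each a sum of five Gaussian deflections
(P, Q, R, S, T) with fixed 3-D directions — the same closed-form family
as ECGSYN-style simulators, chosen because ST-segment and T-wave
perturbations have closed-form control. Beat onsets follow a mean heart
rate with i.i.d. Gaussian jitter on the beat period, truncated at ±3 SD
so the beat ensembles remain near-periodic (the working assumption of
the reconstruction stage).

Defaults, with units and rationale:

| parameter | default | why |
| --- | --- | --- |
| sampling rate | 500 Hz | ample for the QRS bandwidth; halves test cost relative to 1 kHz clinical recorders; configurable |
| duration | 10 s | one standard printout page |
| heart rate | 72 ± 2 bpm | normal resting sinus rhythm with mild variability |
| R amplitude / width | 1.0 mV / 12 ms (σ) | typical limb-lead QRS scale |
| P, Q, S, T | 0.12, −0.10, −0.18, 0.35 mV | textbook relative amplitudes |
| measurement noise | 10 µV RMS per channel | clean resting diagnostic recording |

Noise is added independently per channel (electrode noise), not as a
coherent perturbation of the dipole: coherent dipole noise would project
identically into every lead and disproportionately corrupt
near-cancellation leads such as aVL, which is not how electrode noise
behaves. At zero noise the ECG is exactly the Dower projection of the
VCG, so the forward/inverse lead consistency invariant holds to
numerical precision.

Disease classes perturb the dipole in three clinically motivated ways —
a rigid rotation of the electrical axis (clamped to the 20–90° range
reported for infarction), an ST-segment plateau shift along the QRS
axis, and T-wave inversion. Per-class signatures:
HC (0°, 0 mV, upright T), LAD (35°, +0.20 mV, inverted),
LCX (60°, −0.15 mV, upright), RCA (85°, +0.10 mV, inverted). The E
("location not discernible") class has no generative description in the
clinical literature this follows; it is synthesized per record as one of
the three artery signatures at half magnitude (rotation clamped to the
20° floor), which makes it a stand-in, not a claim about the physiology
of indeterminate infarcts.

What the generator does **not** emulate: torso volume-conductor effects,
respiration and baseline wander, arrhythmia, electrode misplacement,
paper creases or stains. Passing tests therefore demonstrate that the
pipeline recovers structure the generator implants under realistic
noise and timing jitter — they do not certify clinical performance.

## Digitization

The renderer draws a standard 3×4 page (25 mm/s, 10 mm/mV, red
millimeter grid, 10-s rhythm strip) like a pen recorder: each pixel
column is inked over the full vertical span the signal sweeps during
that column's time slice, with anti-aliased (coverage-shaded) boundary
pixels and a minimum pen thickness of 1.2 px. Time zero sits exactly on
the region's first pixel column and advances at the calibration frame's
own scale, so geometry and calibration agree to sub-pixel accuracy.

Digitization removes the grid by per-channel color thresholds (default:
near-neutral pixels darker than 120/255; Otsu thresholding as the
automatic fallback for grayscale scans) and then decodes the pen path
per lead region:

- per column, disjoint pixel runs are disambiguated by keeping the run
  nearest the row baseline (overlap from an adjacent row);
- the partially shaded pixels bordering a run refine its vertical
  extent to sub-pixel accuracy;
- the signal value at each column boundary is taken as the midpoint of
  the overlap of the two adjacent ink spans; a span that overshoots
  both of its boundary values contains a local extremum, recorded as an
  extra knot at the column center (this preserves R-peak amplitudes
  that a plain span mean would attenuate);
- the knot sequence is resampled to the target rate by cubic spline
  (at 144 dpi a pixel column spans ~7 ms, wider than a 2-ms sample
  interval, and the narrow QRS needs better-than-linear interpolation).

With these conventions a 144-dpi noise-free render digitizes back with
per-lead R² ≥ 0.99. Skew correction, stain inpainting and OCR are out
of scope.

## Poincaré-ensemble Karhunen–Loève reconstruction

Each lead's observed 2.5-s segment is delay-embedded with dimension 3
and delay 10 samples (20 ms at 500 Hz) by default. `estimate_embedding`
implements the standard recipes (first minimum of smoothed average
mutual information for the delay; false-nearest-neighbor fraction below
1 % with a Theiler window for the dimension) for users who want
data-driven values, but the pipeline uses the fixed defaults: the
Poincaré section has its normal along the first embedding coordinate,
so crossings only depend on the raw signal and the embedding choice is
not load-bearing there.

Sectioning conventions:

- the section level is 50 % of the dominant peak amplitude, with the
  crossing direction matching the dominant polarity (so inverted-QRS
  leads section on their own upstroke);
- crossings closer than 0.45 of the median RR interval (measured by a
  Pan–Tompkins-style detector on the rhythm lead) to the previous kept
  crossing are discarded — without this refractory rule a tall T-wave
  re-crosses the level inside the same beat;
- segments between successive crossings are resampled to the median
  segment length by linear interpolation.

The Karhunen–Loève basis diagonalizes the second-moment matrix of the
resampled segments (covariance about zero, not about the ensemble mean,
so a beat is represented directly as `g(t) = Σ αᵢφᵢ(t)` with no separate
mean term, and a single repeated beat yields a rank-one basis equal to
that beat's shape). The truncation order is the smallest explaining
≥ 95 % of the trace; eigenvalues are clipped at zero against round-off.

Missing-part synthesis uses the rhythm lead as the timing and amplitude
reference. Both leads are simultaneously recorded, so the target lead's
observed window is cut at the rhythm lead's crossing intervals
(simultaneous sectioning), giving phase-consistent beat pairs. A
least-squares linear map from rhythm-lead KL coefficients to target-lead
KL coefficients is fitted on those pairs (it reduces to a scalar ratio
when both bases are rank one, i.e. to proportional leads) and applied to
every rhythm-lead beat outside the observed window. Synthesized beats
are written onto the rhythm lead's own inter-crossing intervals — which
aligns their R-peaks with the rhythm lead's R-peak times by
construction — and the partial beats before the first and after the
last crossing are filled by wrapping the adjacent beat template
periodically. Observed samples always pass through exactly, so a fully
observed lead reconstructs to itself with R² = 1. If the observed
window contains no complete rhythm-lead beat, the lead falls back to
its own Poincaré section (and, with no usable pairs at all, to scaling
the mean observed beat); the per-lead report flags this.

## ECG → VCG

The default transform is the standard inverse Dower matrix from the
eight independent leads (I, II, V1–V6); any 3×8 full-row-rank matrix
can be injected (e.g. an infarction-specific empirical transform, whose
published coefficients are not available). III and the augmented limb
leads are never consumed — they are linear in I and II, and recomputing
them avoids inconsistencies between independently reconstructed leads.

## Octant features

Octant index = `1 + 4·[X<0] + 2·[Y<0] + [Z<0]`: octants 1–4 share the
X ≥ 0 half-space and 5–8 the X < 0 half-space, matching the clinical
reading of infarct-driven transition shift between left and right
sides; the convention is configurable in the sense that any re-mapping
is a permutation of the eight labels. Exact zero vectors carry no
direction and keep the previous sample's octant. Statistics of
unvisited octants take the fill value 0 so every record yields the same
161 finite, frozen-order features.

Group conventions: sojourn times are in seconds; transition-rate
statistics (SlowTran/FastTran/MeanTran/VarTran) are computed over 1-s
sliding windows (every sample shift) of the octant-change indicator;
arrival/departure rates divide event counts by the record duration.

Topology metrics of the 8-node directed weighted transition network
(self-loops excluded): degrees and strengths are definition-level;
clustering is Fagiolo's directed weighted coefficient (cube-root
weights normalized by the maximum); assortativity is the Pearson
correlation of source out-degree vs target in-degree across directed
edges (0 when fewer than two edges or degenerate variance);
transitivity is computed on the symmetrized unweighted graph; path
metrics use edge length 1/weight, average over reachable ordered pairs
only, and global efficiency averages inverse distances over all ordered
pairs; eccentricity, radius and diameter are taken over the largest
strongly connected component (ties broken toward the component holding
the lowest octant index; nodes outside report 0); betweenness is
normalized by (n−1)(n−2) with n = 8. Modularity is the exact maximum of
Newman's Q over all partitions of the connected octants — with at most
8 nodes the 4140 partitions are cheaply enumerable, the feature is a
*maximized* modularity by definition, and an exact optimum (unlike a
greedy one) is reproducible by an independent oracle. Every one of the
85 metrics is checked against a brute-force reimplementation over an
exhaustive family of small graphs.

One inventory note: the four group sizes are frozen at 48/12/16/85
(161 total) from the feature table this design follows, whose prose
elsewhere quotes 151 and internally inconsistent sub-counts; the row
inventory wins.

## Selection and balancing

Features are z-standardized before PCA (group scales differ by orders
of magnitude), so the decomposition is of the correlation matrix;
constant columns get weight 0. The contribution weight of feature k is
`w_k = Σᵢ βᵢ c²ₖᵢ` over the components explaining 80 % of variance, and
the selected subset is the smallest weight-sorted prefix holding 80 %
of total weight (ties broken by feature name for determinism). The
Gini ranking uses a seeded random forest (200 trees) with the cutoff at
the largest consecutive drop in sorted importance.

Borderline-SMOTE follows the Borderline-1 scheme: minority samples with
at least half but not all of their k = 5 nearest neighbors in other
classes form the danger set (falling back to the whole minority class
when empty, e.g. for well-separated clusters); synthetic samples are
uniform convex combinations with own-class nearest neighbors. Original
rows are preserved verbatim, counts equalize to the majority, and every
synthetic row carries a flag so evaluation can assert that no synthetic
sample crosses a train/test boundary. Balancing is applied only inside
training folds.

## Hierarchical classification and evaluation

The four levels (HC vs MI; E vs localizable; LAD+LCX vs RCA; LAD vs
LCX) are trained independently on their ground-truth-relevant subsets,
each with its own base model — default CART for level 1 and SVM
(RBF, C = 10, standardized inputs) for levels 2–4 — and optional
per-level feature subsets. Prediction walks the tree top-down and
returns the decision path for audit, so the leaf label is always
consistent with its path. Training a level whose classes are absent
raises an error naming the level; the cross-validation harness instead
skips such levels (needed for two-class control experiments).

Evaluation is repeated stratified k-fold (default 10-fold); each
level's accuracy is measured on the ground-truth-relevant test subset
with that level's binary decision, so a level is not penalized for
upstream mistakes — matching how per-level accuracies are convention-
ally reported for hierarchical classifiers. Fold counts are downgraded
with a warning when the smallest class is smaller than the fold count.
Everything is seeded and bit-reproducible with deterministic base
models.

## Problem sizes used in validation

The shipped validation uses cohorts of 50 records per class for
parameter recovery, 20 mixed-class records for the masked-reconstruction
experiment, and one 10-s record for structural checks; the topology
oracle sweep covers all ≤3-node directed graphs with weights in {1, 2}
(729) plus 2,000 seeded 4-node graphs. These sizes make the full suite
run in about a minute while leaving all statistical margins wide
(accuracies at 100 % vs a 90 % bound; median R² ≈ 0.97 vs a 0.95
bound).

## Known limitations

- Reconstruction assumes quasi-periodicity; arrhythmic or highly
  non-stationary rhythms violate the beat-ensemble premise and are out
  of scope, as is operation without any full-length reference lead.
- The E class is a synthetic stand-in; nothing here shows that real
  indeterminate infarcts are separable.
- The published empirical MI-aware ECG→VCG transform is not available;
  inverse Dower is the documented default.
- Digitization handles clean scans; skew, creases and annotation
  overlap are not modeled by the renderer and not corrected by the
  tracer.
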