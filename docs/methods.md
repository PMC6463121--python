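# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `lpstopo`, in the order the pipeline applies them.

## Parcellation

The atlas has 84 ROIs: the 42 Brodmann areas (1–11, 13, 17–25, 27–47
excluding 12, 14–16, 26) once per hemisphere.  Indices 0–41 are the left
hemisphere in ascending BA order, 42–83 the right.  Lobe labels use a
five-way scheme (frontal, parietal, temporal, occipital, limbic); BA13
(insula) is grouped with limbic, the conventional bucket for sub-lobar
cortex when only five labels are available.  All serialized artifacts carry
`BA<number>_<L|R>` labels so files are self-describing.

## Lagged phase synchronization

Signals are segmented into non-overlapping 2-s epochs (512 samples at
256 Hz; trailing partial epochs discarded).  Each epoch is Hann-tapered and
DFT'd; cross-spectra are averaged across epochs **before** the coherency
ratio is formed, and the band value is the **peak** of the per-bin LPS over
the band's bins (a mean-aggregation option exists but is not the default).
The estimator (taper, epoch-first averaging, peak-after-averaging) is a
choice this package fixes and documents; other spectral front ends would
give slightly different absolute values.

Conventions for degenerate cases:

* When `1 − Re[f]² < 1e−12` (numerically perfect real coherency) the LPS is
  defined as 0: a purely instantaneous coupling has no lagged component.
* Zero-power bins contribute 0 and are counted on the result object.
* Band masks are inclusive (`lo ≤ f ≤ hi`); adjacent bands share their
  boundary bin, which is harmless under peak aggregation.

Matrices are symmetrized exactly (averaging the negligible floating-point
asymmetry of the einsum), zero-diagonal, and normalized by the off-diagonal
maximum.

## Graph construction

Proportional thresholding keeps the `k = round(pt/100 · n(n−1)/2)` largest
off-diagonal weights (round-half-away-from-zero; at n = 84, PT = 20% this
gives exactly 697 edges).  Ties at the k-th weight are broken by ascending
(row, col) index after a stable sort, so equal weights — possible after
max-normalization — cannot make results run-dependent.  Pruning removes
only zero-degree nodes and records their atlas indices; pruned graphs may
still be disconnected, which downstream measures handle explicitly.  The
default threshold sweep covers 35%→1% in 1% steps.

## Deterministic measures

* **L** averages finite shortest-path lengths only; disconnected pairs are
  excluded from the mean and their count reported, so low-PT sweep rows
  remain interpretable.
* **E_glob** uses the 1/∞ = 0 convention; disconnected pairs contribute 0.
* **E_loc** of a node is the global efficiency of the subgraph induced by
  its neighbors (0 for degree < 2); the average runs over all retained
  nodes.
* **ACC** averages `2T/k(k−1)` over all retained nodes, counting
  degree < 2 nodes as 0.
* **Betweenness** is exact Brandes betweenness with fractional counting
  over equal-length shortest paths; unnormalized values are canonical, and
  a normalized variant (÷ (n−1)(n−2)/2) sits behind a flag.
* **LCP-corr** is the sample Pearson correlation, over existing edges with
  at least one common neighbor, between the common-neighbor count CN and
  the number of links among those common neighbors (LCL).  It is undefined
  (NaN, not an error) with fewer than two qualifying edges or a constant
  vector; undefined values are excluded pairwise in group statistics, with
  counts reported.

Internally distances come from unweighted BFS (`scipy.sparse.csgraph`),
triangles from adjacency triple products, and betweenness from networkx;
the test suite cross-checks every measure against an independent
brute-force oracle (Floyd–Warshall distances, matrix-power path counts,
explicit CN/LCL enumeration) on hundreds of small random graphs at 1e−10.

## Null models and stochastic measures

Stochastic measures never report a bare number: every result carries the
mean, standard error, realization count and seed.  All are computed on the
largest connected component when the graph is disconnected, with the
coverage recorded.

* **Degree-preserving randomization** uses Maslov–Sneppen double edge
  swaps (target 10 successful swaps per edge, proposal budget 20× the
  target).
* **Latticization** uses the same proposals but accepts a swap only when
  it strictly reduces the summed circular node-index distance of the two
  edges; acceptance decays to zero as the edge set converges, so proposal
  exhaustion there is convergence, not failure.  On a ring lattice the
  procedure is near-idempotent.
* **Small-worldness** ω = mean(L_rand)/L − ACC/mean(ACC_latt): ≈0 for
  small-world graphs, strongly negative for lattices, positive for random
  graphs (calibrated in the tests: ring lattice < −0.4, dense
  Erdős–Rényi > 0.3, Watts–Strogatz n = 84/k = 8/p = 0.1 within ±0.3).
* **ω_E** = E_glob/mean(E_glob_rand) − E_loc/mean(E_loc_latt) is this
  package's construction by analogy for an efficiency-based small-world
  index; the exact published formula behind the index it stands in for is
  not available, so ω_E is a declared substitute, not a reconstruction.
  `small_worldness_both` computes ω and ω_E on shared null ensembles,
  halving the rewiring cost.
* **Modularity** runs multilevel (Louvain) community detection with 20
  seeded restarts at resolution 1 and reports the best Q with its
  partition.
* **Structural consistency** σ_c removes a random 10% of edges, corrects
  the eigenvalues of the remaining adjacency to first order using the
  removed part as the perturbation (Δλ_k = x_kᵀ ΔA x_k), scores all
  unobserved pairs by the reconstructed matrix, and reports the fraction
  of removed edges among the top-|removed| scores, over 10 repetitions.

Default realization counts (50 nulls for publication-grade runs, 20 in the
demo pipeline; 10 repetitions for σ_c) balance the standard error of the
null means against runtime; the demo sizes keep the full 25-subject,
six-band pipeline within a few minutes on one CPU.

## Network-based statistic

Edge-wise pooled-variance two-sample t-tests (sign = mean(A) − mean(B);
zero-pooled-variance edges get t = 0) run on the weighted, pre-threshold
matrices.  A one-direction primary threshold of t = 2.6 forms the
suprathreshold graph per contrast (A>B keeps t > 2.6, B>A keeps −t > 2.6);
connected components are sized by edge count (node count behind a flag).
The null distribution of the maximal component size comes from random
relabeling of whole subjects; the corrected p-value is
`(1 + #{perm max ≥ observed}) / (1 + n_perm)`, so the observed labeling is
always in the null and p > 0.  With 12 vs 13 subjects the labeling space
(~5.2M) exceeds the default 20,000 permutations, so distinctness is not
enforced; a warning fires when it would be.  Note the operative threshold
t = 2.6 at 23 degrees of freedom corresponds to a two-tailed p of 0.016,
not 0.05; the pairing of those two numbers in the emulated protocol is
internally inconsistent and t = 2.6 is taken as operative.

## Group statistics

Mann–Whitney U is two-sided, exact when the sample-size product is ≤ 400
and tie-free, asymptotic with tie correction otherwise; two identical
constant samples give p = 1.  AUC equals U/(n₁n₂) with ties counted half;
AUPR is the step-wise average-precision estimator, whose chance level is
the positive prevalence.  The AUC/AUPR positive class is the group with the
higher mean for each measure, and the orientation is recorded — so AUC is
≥ 0.5 by construction and comparable across measures.  Whole-brain measure
comparisons are intentionally uncorrected (no feature selection is
happening); nodal contrasts are Benjamini–Hochberg corrected across the 84
areas.  Nodal percent change is (UWS − MCS)/MCS of group means, undefined
when the reference mean is 0.  Clinical correlations (Pearson and Spearman
against CRS-R) exclude undefined measure values pairwise and require at
least 3 pairs.

## Synthetic cohort

The generator emulates the study conditions rather than any particular
patient: 12 UWS and 13 MCS subjects; CRS-R drawn per subject from
N(5, 1) and N(13, 4) respectively, truncated at 0 (a scalar per subject;
intra-subject rater variability is not modeled); six bands with all group
structure confined to β1; ~5 min of signal (150 2-s epochs) at 256 Hz.

**Signal model.** Each ROI carries unit-variance white noise plus a weak
(amplitude 0.3) background oscillation at a frequency drawn from the broad
2–30 Hz range.  Coupling is sinusoidal: a coupled pair shares a carrier on
a DFT bin centre inside the target band, phase redrawn per epoch, reaching
the second ROI with a 90° lag (the lag that maximizes the imaginary
coherency).  Bin-centred carriers matter: an off-grid carrier leaks power
across bins and the measured LPS then depends on the carrier's alignment
with the DFT grid, an artifact that would masquerade as between-subject
variability.  For a bin-centred carrier of amplitude s against unit noise
the asymptotic LPS has the closed form `((Ks²)/(Ks²+1))²` with `K = N/6`
(N = epoch samples, Hann taper), which the tests verify and the generator
inverts.

**Planting effects on the measured scale.**  Effect sizes are standardized
decreases of *LPS weight*: per-subject planted-edge LPS targets are drawn
from N(0.92, 0.03) for MCS and the mean is lowered by
`effect_size × 0.03` for UWS, then converted to carrier strengths through
the inverse response.  Planting in coupling space instead would deliver a
smaller, skewed contrast because the coupling→LPS map is compressive.

**Coherent subnetwork drive.**  The default planted deficit is the
complete bipartite coupling of 4 left-frontal with 5 right-parietal ROIs
(20 edges over 9 nodes) — a compact connected motif of the kind NBS is
designed to recover.  Complete-bipartite edge sets are realized as a
single coherent source: all frontal nodes receive the carrier at 0°, all
parietal nodes at 90°, so LPS appears exactly on the planted cross pairs
while within-set pairs share the carrier at zero lag and show nothing (the
same property that makes LPS robust to volume conduction).  Arbitrary edge
sets fall back to independent per-edge carriers, which is noisier for ROIs
participating in many planted edges.

**Group-independent structure.**  Every subject also carries a strong
backbone (40 edges at LPS ≈ 0.97) and a broad weak background (300 edges,
subject-level mean LPS ≈ 0.2 ± 0.05), both drawn once per cohort on pairs
away from the effect subnetwork.  The backbone keeps the normalization
maximum on edges unaffected by the contrast; the background gives overall
functional connectivity a realistic group-independent between-subject
spread, so the overall-FC bias check behaves as in the emulated study (no
group difference in overall FC while a specific subnetwork differs).  The
default signal-cohort effect size is 2.5 LPS-SD units — a clearly
significant deficit, matching the strongly significant subnetwork the
pipeline is designed to exhibit; because the coherent drive gives one
strength draw per subject, cohort-level detection is nearly all-or-nothing
and a marginal default would make the demonstration a coin flip.

**Fast path.**  `generate_connectome_cohort` skips signal simulation and
draws weighted matrices directly: a fixed edge profile N(0.3, 0.08) shared
by all subjects plus subject noise N(0, 0.05), with the planted edges
shifted down by `effect_size × 0.05` in the affected group (an exact
standardized mean shift) and out-of-range weights clipped and logged.  The
statistical calibration simulations (NBS type-I error and power) use this
path at the prescribed standardized shift 1.5.
`generate_segregation_cohort` plants extra within-module weight in the
UWS-like group (6 random modules; boosts 0.16 vs 0.06 on a 0.3 base),
producing the segregation-over-integration profile — higher ACC, E_loc and
LCP-corr, lower ω — at ≥0.8 power for the 12-vs-13 comparison.

**What the synthetic data does not emulate.**  1/f spectra, non-sinusoidal
and non-stationary rhythms, volume-conducted mixtures beyond zero-lag
sharing, artifacts, inverse-solution leakage between nearby ROIs, and any
spatial correlation structure of real cortical activity.  Passing tests
therefore validate the *estimators and statistics*, not claims about real
EEG; absolute measure values in real data will differ with the spectral
front end.

## Recovery characteristics of NBS at these settings

With t = 2.6 at 23 degrees of freedom, roughly 0.8% of the 3,466 null
edges (≈28) exceed the one-direction threshold by chance, which puts the
null suprathreshold graph near its percolation threshold.  Spurious
clusters that touch the detected component inflate it, so although a
planted 20-edge deficit at standardized shift 1.5 is *detected*
(corrected p < 0.05) in essentially every run, the edge-Jaccard between
the detected component and the planted set exceeds 0.5 in only about
three quarters of runs — under this package's generator and equally under
an idealized iid-normal simulation.  This is a property of the threshold,
the group sizes and component-forming itself, not of the implementation;
the acceptance suite states the stricter ≥80% recovery bar and reports the
measured rate.

## Reproducibility

Every stochastic routine takes an explicit seed and derives all internal
randomness from `numpy.random.default_rng`; the rewiring kernel (numba)
consumes pre-drawn arrays so JIT compilation cannot affect the stream.
Pipeline artifacts are written as tab/comma-delimited UTF-8 text with LF
endings and `%.17g` floats (bit-exact float64 round trips; matrix reads use
pandas' round-trip parser), and each run directory records the config hash,
seeds and library versions.  Identical config and seed give byte-identical
outputs.
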