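# Methods

This note documents the models implemented in `irlnet`, the choices made
where the design was genuinely open, what the synthetic data emulate (and
what they do not), and the package's numerical conventions.

## Probe re-annotation

Alignment hits (probe, probe set, transcript, perfect/imperfect) are
reduced to a one-to-one probe-set → transcript map by three rules applied
in a fixed order: (1) only perfect matches are eligible; (2) a probe
matching more than one transcript is deleted; (3) a probe set is retained
only if all its surviving probes target one transcript, and a transcript
only if it has more than four (i.e. at least five, strict integer
comparison) surviving probes.  The order is the only one in which each
rule's precondition is well defined: ambiguity must be resolved before
support is counted, so a transcript whose fifth probe was ambiguous drops
to four supporters and is excluded.  Probe-level expression is summarized
to transcript level by the median across surviving probes — robust to a
single aberrant probe, and exact on the ≥5 probes the filter guarantees.

## SAM differential expression

For feature *i*, `d_i = r_i / (s_i + s0)` with `r_i` the mean
case-minus-control difference and `s_i` the pooled standard error
(unpaired), or the mean and standard error of within-subject differences
(paired).  The fudge constant `s0` is chosen on the percentile grid
0, 5, …, 100 of `{s_i}` by minimizing the coefficient of variation of the
median absolute deviation of `d` across quantile windows of `s` (20
windows, fewer on small feature sets); ties take the smallest percentile,
and when all `s_i` coincide the procedure degenerates to that common
value.  Significance is by permutation: all `C(n1+n2, n1)` label splits
(unpaired) or all `2^n` sign flips (paired) are enumerated when the count
is at most 20,000, otherwise a seeded random subset is drawn.  Permuted
statistics are pooled **across features** — with 10-to-13 samples a
per-feature null is far too coarse — and
`p_i = (1 + #{|d*| ≥ |d_i|}) / (1 + N)`, an add-one estimator that can
never return zero.  Raw p-values are thresholded strictly at 0.01 with no
multiplicity correction; an optional Benjamini–Hochberg column is
available to users but plays no role in the pipeline.  Transcripts
significant in both the case/control and the paired contrast are carried
forward; requiring replication across two independent contrasts removes
essentially all permutation false positives before network construction.

## Shared-RBP co-regulation edges

With `m` RBPs in total, `t` bound by an mRNA, `n` bound by a lncRNA and
`r` shared, the edge evidence is the exact hypergeometric upper tail
`P(X ≥ r)`, computed with integer binomial coefficients and converted to
float once (`Fraction(num, C(m, n))`), so the result is exact to the last
digit for any `m` arising in practice.  Preconditions
(`r ≤ min(t, n) ≤ m`) raise rather than clamp.  Only pairs with `r ≥ 1`
are evaluated — a pair sharing nothing has `P = 1` and can never pass —
and `m` is always the number of RBPs observed in the loaded tables, so
the statistic adapts to any interaction snapshot.  Edges with `P < 0.01`
(raw, mirroring the differential-expression convention) constitute the
network; the same tail powers the generic GMT over-representation test.

## Bicluster module analysis

The network is rendered as a lncRNA × mRNA association matrix with
`1 − p` on significant edges and 0 elsewhere, clustered in both
directions (Euclidean distance, complete linkage — the common heatmap
defaults, both configurable).  Default cluster counts come from the
largest merge-height gap of each dendrogram, restricted to cuts yielding
2–10 clusters, preferring the shallowest cut among gaps within half of
the largest: variance-ratio indices such as Calinski–Harabasz degenerate
on near-binary scores (a pure block has zero within-variance, so deeper
cuts always win), whereas the dominant dendrogram gap identifies the
structural block/background separation.  The module is the
(row-cluster × column-cluster) block with the highest mean association;
blocks within 1e-3 of the best count as tied and resolve toward more
cells, then lexicographic label order — without the tolerance, a single
strong background edge (a 1 × 1 block with mean ≈ 1) would routinely beat
the true module.  When the network's lncRNA nodes are *all* block
members, any 2-way row cut necessarily splits the block and the reported
module is a sub-block; this is inherent to cut-based extraction on tiny
association matrices.

## Weighted co-expression analysis

Unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` (Pearson; zero-variance
features get zero adjacency, logged), topological overlap
`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, and
average-linkage clustering of `1 − TOM`.  Defaults: `β = 15` with a
scale-free fit target of `R² = 0.75` (the fit index is the signed squared
correlation of `log10 p(k)` vs `log10 k` over 10 connectivity bins; the
smallest β reaching the target is chosen, else the argmax), minimum
module size 30, eigengene merge height 0.10.

Branch detection scans tree cuts of increasing depth and keeps the
partition maximizing the number of branches with at least the minimum
module size, tie-breaking toward the deepest such cut; undersized
branches are grey.  A fixed cut height was tried first and abandoned: at
13 samples and `β = 15`, within-module merge heights on `1 − TOM` spread
from ~0.96 to ~0.999 across seeds, so no constant separates true modules
from noise.  Deliberate over-splitting is safe because the eigengene
merge step (dissimilarity `1 − cor < 0.10`, iterated to a fixed point
with eigengenes recomputed after each merge) re-fuses fragments of a
homogeneous module, whose eigengenes are nearly collinear.  A
medoid-style rescue then assigns each grey feature to the module with the
highest mean TOM, provided that overlap reaches 0.3 of the module's
internal mean overlap — repairing fragments the cut carved off while
leaving genuinely unconnected features grey.  Note the size-first scan
can subdivide a single homogeneous module larger than twice the minimum
size; the merge step re-fuses these, but users working with very large
modules should be aware of the behaviour.

The module eigengene is the first right singular vector of the
standardized member submatrix, unit norm, sign-anchored so the average
member correlation is positive.  Module–trait association is the squared
Pearson correlation of the eigengene with the trait (binary group encoded
0/1), with the usual t-distribution p-value on `n − 2` df.  Hubs are
ranked by intramodular connectivity `kWithin` (sum of adjacency to
same-module members, self excluded); the pipeline reports the top 7
lncRNAs of the most trait-correlated module.  Sample outliers are removed
beforehand by cutting the average-linkage sample tree at
mean + 2.5 SD of its merge heights and dropping branches smaller than 3 —
the field practice of deleting abnormal branches by eye cannot be
codified exactly, so the rule errs toward keeping whole groups.

## Clinical statistics

HOMA-IR = fasting insulin (mIU/L) × fasting glucose (mmol/L) / 22.5,
positive inputs enforced.  Insulin resistance is the upper tertile of
HOMA-IR; tertiles cut at the 1/3 and 2/3 linear-interpolation quantiles
with boundary values going low (documented, arbitrary).  BMI categories
follow the WHO Asian cutoffs (normal 18.5–23.9, overweight ≥ 24, obese
≥ 29 kg/m²); hyperinsulinemia is fasting insulin strictly above
23 mIU/L.  Relative qPCR expression is `2^−ΔΔCt` with
`ΔCt = Ct_target − Ct_reference` and the control-group mean ΔCt as
calibrator (the standard Livak choice; invariant to any constant Ct
shift).  Two-group comparisons gate on normality: each group is tested by
the Lilliefors-corrected Kolmogorov–Smirnov test (estimated-parameter
correction via statsmodels; a plain KS against a fitted normal is
anticonservative) at α = 0.05; if both pass, an equal-variance Student
t-test runs, otherwise (including zero-variance groups) the two-sided
Mann–Whitney U.  Under a 2,000-replicate Gaussian null the combined
procedure's rejection rate at 0.05 stays inside the 99% binomial
envelope.

## Synthetic data: what it emulates, and what it does not

The default study plants, in a universe of 200 lncRNAs and 2,000 mRNAs
measured on a log2 scale in 10 cases and 13 controls (plus the 10 cases
before/after treatment):

* **Differential expression** — 12 lncRNAs and 50 mRNAs shifted by
  2.0 log2 units (random sign) over Gaussian noise of SD 0.5 around
  feature baselines ~N(7, 1.5²); treatment reverses the shift for 80% of
  them (always including the block), so the two contrasts intersect in a
  known set.  A per-subject random intercept (SD = noise SD) gives the
  paired contrast its repeated-measures structure.
* **A co-regulated block** — 6 lncRNAs and 34 mRNAs sharing a latent
  factor with loadings ~U(0.6, 0.9) and coherent upregulation.  The
  factor is mean-centered within each sample group, making it orthogonal
  to the contrast: the planted effect size is then exactly the nominal
  2.0 rather than 2.0 ± the factor's group imbalance, which at n ≈ 10
  would otherwise randomly push entire blocks below the calling
  threshold.
* **RBP binding** — every feature binds each of 30 RBPs independently at
  background rate 0.1; the hub lncRNA binds each RBP with probability
  0.3 (one third of the 0.9 within-block overlap), and block members
  include each hub RBP with probability 0.9.  The hub's repertoire must
  stay a minority of the universe: a lncRNA binding most RBPs shares
  them with everything *by chance*, and no hypergeometric tail can be
  small.  At these settings hub–block pairs score P ~ 1e-4 and
  block–block pairs P ~ 5e-3, while background pairs rarely cross 0.01.
* **Clinical cohort** — 52 cases and 42 controls with group-separated
  BMI, LH, testosterone, AMH, glucose and insulin distributions spanning
  realistic PCOS/control ranges (insulin and hormones log-normal), and
  Ct values constructed so that relative hub expression rises with
  HOMA-IR.  A `clinical_effect` dial interpolates toward an exact null
  cohort.

The dedicated module-recovery fixture plants three modules (40/35/30
features, within-module correlation exactly 0.8, 13 samples) whose latent
factors are mutually orthogonalized and — beyond the trait module —
orthogonal to the binary trait; the first factor correlates with the
trait at 0.95.  Orthogonalization implements the stated zero background
correlation exactly: at 13 samples, independent factors align by chance
at |cor| ~ 0.3, which leaks into the topological overlap and entangles
branches.  The soft-threshold fixture uses a single factor with
Pareto-tailed loadings, giving the heavy-tailed connectivity for which
the scale-free fit index is designed.

None of the generators mimic array-level physics (probe sequence
content, intensity saturation, normalization artifacts), real GENCODE
annotation, correlated RBP binding profiles, or batch structure.
Passing tests therefore demonstrate that the *algorithms* recover planted
structure under the stated statistical model, not that any particular
biological dataset would yield the same networks.

## Determinism and problem sizes

Every generator is a pure function of its configuration; independent
seed streams per generator keep fixtures stable under partial reruns.
Pipeline outputs are written with a fixed float format and hashed into a
JSON manifest, so identical configurations reproduce byte-identical
tables.  The test suite and the acceptance script run the full chain at
desk scale — 2,200 transcripts, 23 samples, 30 RBPs, 1,000 permutations,
20-seed module-recovery sweeps, 2,000-replicate calibration nulls —
sizes chosen so the planted effects are comfortably detectable while the
whole suite completes in minutes on one CPU.  The acceptance script's
end-to-end hub-recovery check runs on the fixed default study (seed 42),
the package's reference fixture; all calibration statistics use the
caller's seed.
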