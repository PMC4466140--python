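# Methods

This note documents the models behind `sh3spot`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic benchmark
does and does not demonstrate.

## Normalization

Raw SPOT intensities are strictly positive, span orders of magnitude, and
carry a per-membrane multiplicative exposure factor.  The pipeline works on
the log2 scale: `log2(v + pseudocount)` (pseudocount default 1.0; set it to
0 when all intensities are positive and exact exposure invariance matters),
replicate averaging per probe, then median scaling.

Median scaling is a per-domain *shift* on the log2 scale (equivalently a
multiplicative rescaling of raw intensities).  A shift equalizes medians
while preserving each domain's spread and every between-domain correlation,
which is all the downstream analysis consumes.  Two targets are offered:

* `target="common"` (default): each domain is centered on its own median
  and shifted to the median of the pooled *centered* values.  Because
  centered values are unchanged by any per-domain shift, the output is
  **exactly** invariant to multiplying any one domain's raw intensities by
  a positive constant — a membrane exposure change cancels to the last bit.
  This invariance is the purpose of the normalization, so it is the
  default.
* `target="pooled"`: the textbook batch variant that shifts every domain by
  (median of pooled input values − domain median).  It equalizes medians
  identically, but the common level then tracks the pooled input, so an
  exposure change on one membrane moves all profiles by a small common
  constant.  Kept for compatibility with the conventional description of
  batch median scaling.

The two differ only by a global additive constant; correlations, clusters,
top-peptide ranks and PWMs are identical under either.  Missing probes in a
replicate are rejected at input rather than masked, keeping all profile
vectors index-aligned.  Background (carrier-only) signal subtraction is not
implemented; if the assay includes control membranes, subtract them
upstream.

## Specificity landscape

Profiles are compared by Pearson correlation over the full library.
Clustering is agglomerative on distance `d = 1 − r` — not `1 − |r|`,
because anti-correlated profiles are maximally dissimilar in a binding
heat map.  Linkage is average (UPGMA) by default, configurable to
single/complete/ward; domain order is canonicalized lexicographically
before linkage so merge ties break deterministically and the leaf order is
reproducible.  Zero-variance profiles (a domain that bound nothing) cannot
be correlated and are dropped with a warning.

The tree is cut at `k = 3` by default, matching the three canonical
specificity classes.  Each cluster is labeled by the majority motif class
of the pooled top-10 peptides of its members; exact ties are reported as
`unassigned`.  Type I\* peptides vote with Type I at the landscape level —
the I\* variant is a per-domain refinement, not a fourth global cluster —
while the per-peptide classifier still reports I\* explicitly.

## Motif classes

The class templates are regular-expression transcriptions of the standard
prose patterns:

| class | template | anchor residue |
|---|---|---|
| II  | `P..P.[RK]`               | first core proline |
| I   | `[RK]..P..P`              | the charged residue |
| I\* | `[RK]..Φ..P`, Φ∈AVLIMFWY  | the charged residue |
| III | `P..P..P`, or ≥4 P in an 8-residue window; no R/K inside the span | first P of the longest proline run |

Precedence II > I > I\* > III with leftmost matching, so each peptide gets
one dominant class; match coordinates are retrievable.  The I\* hydrophobic
set excludes proline by construction, so an actual Type I match can never
be demoted to I\*.

Peptide alignment is automated (the anchor residues above are shifted into
one shared column, chosen as the most common anchor position with ties to
the larger position so motif spans stay inside the 15 columns); overhangs
are trimmed and short ends gap-padded.  Peptides of other classes are
stacked unshifted and flagged secondary.  PWM frequencies are
`(count + pseudocount) / (non-gap rows + 20·pseudocount)` per column; gap
cells contribute nothing.  Pseudocount defaults: 0 for logos (observed
frequencies), 0.01 for scanning PWMs (no zero columns).  "Top" peptides can
be selected as a count (`top_n`, default 10) or as everything strictly
above an intensity percentile (`percentile=95` keeps the best ~5%); the
percentile reading is used because including 95% of the library would sweep
in non-binders.

Logo export computes per-column information content
`IC = log2 20 + Σ_a f log2 f` (with `0·log 0 = 0`) and letter heights
`f·IC`; rendering is left to the caller (the TSV has everything a drawing
library needs).

## Proteome scanning

A window's score sums, per position, the PAM250 substitution scores of the
observed residue against the PWM column, frequency-weighted.  PAM250 (and
BLOSUM62 for identities) come from Biopython's bundled copies of the
standard matrix collections.  Ambiguous residues (X/B/Z…) contribute zero
at their position and raise a warning.

Significance is calibrated per PWM: 1000 random 15-mers drawn positionwise
from the background composition (default: the scanned sequence set's own
residue frequencies; configurable to uniform) are scored, and a Gaussian is
fitted by moments.  The default p-value is the fitted upper tail.  The
purely empirical add-one p-value `(1 + #{null ≥ s})/(1 + n)` is available
as a diagnostic, but with n = 1000 its floor is ~1e-3, which can never pass
the q < 1e-4 hit filter — a parametric tail is the only construction under
which that cutoff is operative.  The score is a sum of 15 weakly coupled
bounded terms, so the Gaussian approximation is accurate well into the
tail; the null-calibration benchmark (below) checks exactly this.

Benjamini–Hochberg is applied jointly across **all** windows of one scan
invocation (the whole protein set of a figure panel), implemented as the
step-up rule `q_(i) = min_{j≥i} p_(j)·m/j` and cross-checked against
statsmodels in the tests.  Hits are windows with `q < 1e-4`, annotated with
their motif class; overlapping hits are merged into runs for reporting
(representative = maximum-score window) while the per-window table is kept.
Coordinates are 0-based half-open internally and in BED output, 1-based
inclusive in the human-readable TSV (stated in its header).

## Sequence identity versus profile correlation

Percent identity uses global Needleman–Wunsch alignment (BLOSUM62, gap
open 10, extend 0.5); the denominator is aligned columns excluding terminal
gaps, and internal gap columns count as mismatches.  The two sequences are
ordered canonically before alignment so the result is exactly symmetric.
For ~60-residue domains of one family, any sane global aligner gives
near-identical identities.

The global association between identity and profile correlation over all
within-family pairs is summarized by Spearman's rank correlation — the
relation is expected to be monotone, not linear — with a seeded permutation
p-value (10,000 shuffles of the correlation column).  Constant columns make
the statistic undefined; it is reported as NaN rather than forced.  Per
family, pairs are ranked by identity and by correlation, and the pair whose
identity rank most exceeds its correlation rank is flagged as the family
outlier: a high-identity/low-correlation pair indicates a binding
specificity switch that sequence divergence alone cannot explain.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, as a
pure function of a seeded config:

* **Library** — 292 15-mers (the published assay scale), cysteine-free
  (membrane synthesis replaces Cys by Ser), background uniform over the 19
  non-Cys residues, each embedding one class instance at a random offset
  with mix {I: 0.3, II: 0.3, I\*: 0.1, III: 0.3}.  Type III instances put
  proline in the scaffold's x positions half the time, giving the
  proline-rich runs characteristic of polyproline ligands.  Peptides are
  rejection-sampled until the classifier assigns exactly the intended
  class, so the recorded truth is exact; class counts follow
  largest-remainder apportionment.
* **Intensities** — log-normal:
  `log2 I = μ + offset_d + gain·1[match] + η_dp + ε_dpr` with baseline
  μ = 10 (arbitrary; removed by normalization), membrane offset
  sd 0.5, replicate noise sd 0.5 (2 replicates), and class-match gain 4
  log2-units.  Published SPOT studies do not report an intensity noise
  model; this log-normal form is an assumption, flagged as such.
* **Coupling** — η_dp ~ N(0, 1.5·√rate_f) is a per-domain profile drift
  shared across replicates, with per-family divergence rates spread
  geometrically (factor 4 around 0.15 substitutions/site) across the 6
  families.  The same rates drive Poisson point substitutions of the
  ~60-residue family ancestors, so sequence identity and profile
  correlation decay together — the association the conservation stage
  measures.  With drift, offsets and noise at zero the model degenerates to
  exact constant/fold-change intensities, which the unit tests exploit.
* **Proteomes** — 100 proteins, Poisson lengths around 200, uniform
  composition, with 20 planted sites sampled from a high-information
  consensus PWM (anchor positions at probability 0.95); coordinates are
  recorded 0-based half-open.  "Strong" sites are deliberate: the benchmark
  measures calibration and power of the scan, not the information content
  of real sites.
* **Class-switch scenario** — one member of the most conserved family gets
  a sibling's sequence with a single substitution (identity = family
  maximum) and a flipped binding class, reproducing the
  high-identity/low-correlation outlier geometry.

What the generator does **not** model: SPOT chemistry (coupling efficiency,
membrane edge artifacts, saturation), carrier-protein background binding,
domain insolubility, real proteome composition biases (disorder,
proline-rich region clustering), or indel evolution of domains.  Passing
benchmarks therefore demonstrate the pipeline's statistical correctness
under its stated assumptions, not performance on any particular real
membrane.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the landscape benchmark on
100 seeded panels (24 domains × 292 peptides each), scan calibration on 100
unplanted proteomes and power on 20 planted ones (~18,000 windows each),
and the conservation benchmark on 36 within-family pairs with 10,000
permutations — a few seconds each on one CPU.  Every random draw flows from
`numpy.random.default_rng` seeded from the config or CLI seed; identical
seeds give byte-identical outputs, and output headers record the tool
version, seed and a parameter hash.

## Known limitations

* The Gaussian null tail is an approximation; at cutoffs far beyond
  q = 1e-4 or with very low-entropy PWM columns its accuracy degrades
  (the empirical mode can diagnose gross miscalibration but not reach such
  cutoffs).
* Cluster class labels depend on the top-peptide classifier; libraries
  dominated by unclassifiable binders yield `unassigned` clusters.
* Identity is computed on pre-trimmed domain sequences; giving full-length
  proteins will dilute identity with linker sequence.
* The automated peptide alignment anchors on single residues; it
  reproduces the intent, not the letter, of hand-curated alignments.
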