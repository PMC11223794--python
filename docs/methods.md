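# Methods

## The problem

i-Motifs are quadruple-helical DNA structures formed by cytosine-rich
sequences under mildly acidic conditions: runs of consecutive cytosines
(C-tracts) pair through intercalated, hemiprotonated C·C(H+) base pairs,
with the intervening nucleotides looped out. The experimental readout of
stability is the transition pH — the pH at which half the population is
folded. This package (i) enumerates putative i-motif forming sequences in
DNA under configurable structural constraints, (ii) converts candidates
into a fixed 33-feature vector, (iii) trains feature→label regression
models (e.g. transition pH) with a bi-level AutoML search, (iv) packages
fitted predictors into portable bundles that map raw DNA to a predicted
label and a 0–1 stability score, and (v) computes genome-scale density
statistics (C density, iPM).

## Detection model

A candidate is `k` C-tracts separated by `k−1` loops. Defaults: exactly 4
tracts of 3–5 cytosines, loops of 1–12 nt; the first and last loops are
*side* loops and interior ones *middle* loops, each role with optional
separate bounds (sanity range 1–50). The grammar is canonicalized as
follows; both the scanner and the independent test oracle implement the
same rules:

* Tracts are sub-intervals of maximal C-runs and each maximal run hosts at
  most one tract — equivalently, every loop contains at least one non-C
  base. A run longer than the placed tract spills its leftover cytosines
  into the adjacent loops.
* Candidates use consecutive *eligible* runs (length ≥ the tract minimum):
  no run long enough to be a tract may sit wholly inside a loop. This
  keeps parses unambiguous and prevents physically odd calls in which a
  competent tract is treated as loop sequence.
* Each eligible run is an anchor yielding at most one candidate: the
  minimal-extent valid motif whose first tract lies in that run
  (non-greedy, default) or the maximal-extent one (greedy). Ties on extent
  prefer fewer (non-greedy) / more (greedy) tracts, then the
  loop-localization objective, then the leftmost placement.
* Loop localization: with freedom left in tract offsets, `equal_loops`
  minimizes the population variance of loop lengths; `short_side_loops`
  minimizes the summed side-loop length first, variance second.
* With overlaps disallowed (default), candidates are selected left to
  right, skipping any that intersect an accepted one — deterministic and
  independent of discovery order. Overlap resolution is per strand; a
  both-strand scan therefore reports exactly the union of the two
  single-strand scans, and motif counts obey the reverse-complement
  symmetry used in the tests.
* Input is uppercased; any non-C character (including N) terminates a
  tract; loops reject non-ACGT characters unless `allow_n_in_loops` is
  set. Coordinates are 0-based half-open internally and in BED output,
  1-based inclusive in the TSV report. Reverse-strand motifs are reported
  in C-rich orientation with forward-strand coordinates.

Enumeration cost is the product of per-run placement choices within one
anchor's runs, with early pruning on loop bounds. Because a tract needs
its own run and loops are bounded, pathological inputs (e.g. megabase
poly-C) collapse to zero or few anchors; random genomes scan at roughly a
megabase per second per strand on one CPU.

## Features and normalization

All models consume the same ordered 33 features, frozen in
`imseeker.features.FEATURE_NAMES`: 13 structural descriptors (motif
length; tract count; tract-length mean/min/max/variance; loop count;
loop-length mean/min/max/variance; total loop length; fraction of the
motif inside tracts), 4 mono-nucleotide fractions and the 16 dinucleotide
frequencies (row-major A,C,G,T order). Variances use the population
(divide-by-n) convention; dinucleotide denominators are motif length − 1.
This particular set is this package's interpretation of "33 pre-determined
i-motif features"; bundles store the name list explicitly so a future
replacement set stays self-describing.

Normalization is column-wise affine, fitted on the training split only:
z-score (population SD) by default — several portfolio models (SVR, MLP)
are scale-sensitive — with min–max as an alternative. Zero-spread columns
are flagged and passed through with scale 1.

## Bi-level AutoML

Model selection is a bi-level program: the upper level picks a
(feature-selection, regressor) pair from the portfolios — 6 selector
families (GUS, SFM, SFS, RFE, RFECV, VT) plus a NONE pass-through, times
12 regressor families (RIDGE, DTR, RFR, GBR, SVR, MLPR, ETR, BR, ABR,
STR, HGBR, XGBR), 84 pairs in total — while the lower level tunes that
pair's hyperparameters. The objective at both levels is the mean
out-of-fold R² of the full pipeline under k-fold cross-validation (k=5
default) on the training split, with the selector refit inside each fold
(no leakage). A held-out split (20%, seeded shuffle) is scored exactly
once, after the search ends. Cross-validated rather than resubstitution R²
is used because raw training R² would trivially favour overfitting
ensembles.

**Upper level — Tabu search.** One pair is TPE-evaluated per round; the
tabu list has full memory (the space is tiny, so tenure and aspiration
rules add nothing), and a pair is never scored twice. The next pair is a
seeded random non-tabu neighbour of the incumbent (neighbours differ in
exactly one coordinate); when the neighbourhood is exhausted the walk
restarts at a random unvisited pair, so a budget of ≥ 84 rounds enumerates
the whole space and provably returns the exhaustive argmax (ties broken
lexicographically). `upper_rounds` therefore counts pairs evaluated, which
makes budgets directly comparable across presets.

**Lower level — TPE.** No Bayesian-optimization library is bundled; the
Tree-structured Parzen Estimator is implemented in
`imseeker.automl.tpe`. Trials are split into the top-γ *good* fraction
(γ=0.25) and the rest; per dimension, good and bad densities are Parzen
mixtures (Gaussians at the observations plus a uniform domain prior;
bandwidth = larger neighbour gap, clipped) for numeric dimensions —
log-scaled where declared, integers quantized after sampling — and
pseudo-counted frequencies for categorical ones. Each proposal maximizes
Σ log l(x) − log g(x) over 24 candidates drawn from l. Because every
(fs, model) pair has a flat domain, the conditional "tree" collapses to a
per-dimension product. Two deliberate refinements: a short uniform startup
phase (≤10 trials), and de-duplication on small finite domains — the
objective is deterministic, so re-evaluating an identical configuration
while untried ones remain would waste a trial; this also makes TPE exact
on discrete domains no larger than the trial budget. The TPE stream for a
pair is seeded from (pair, run seed) alone, so results are independent of
upper-level visit order — this is what lets Tabu and exhaustive
enumeration agree configuration-for-configuration.

**Budgets.** Presets (upper rounds × TPE trials): swift_basic 8×10,
balanced 20×25, thorough 40×60, best_performance 84×150 — spanning
minutes to days of single-CPU effort. Failed fits score −∞ and the search
continues; a run errors only if nothing feasible was found.

**Hyperparameter domains** are frozen in `imseeker.automl.space` (e.g.
ridge α log-uniform 1e−3…1e3, tree depths 2–12, ensemble sizes 50–150
log-uniform, XGBoost η log-uniform 1e−3…0.3, MLP layouts of 1–3 layers of
16–128 units). Wrapper selectors are kept affordable inside
cross-validated evaluation: SFS uses cheap inner estimators, a single
shuffle-split for its internal scoring, and interprets its size parameter
as selection *steps* (features added forward, removed backward); RFE/RFECV
eliminate in ~20–30% blocks with small inner CV. These are deliberate
quality/runtime trade-offs for desk-scale hardware; widening them changes
wall time, not code paths. When the user pins a feature subset, the whole
search operates within it.

## Bundles and the stability score

A bundle (`*.imseeker`) is a ZIP with `manifest.json` (schema version,
detection parameters, ordered feature names, normalizer vectors, label
kind and training range, provenance digest — readable standalone),
`model.bin` (joblib-serialized fitted pipeline, format-tagged) and
`checksum` (SHA-256 of both members; loading refuses tampered files and
manifests newer than the reader). Predictions after save/load are
bit-identical. Scoring a sequence runs detection with the bundled
parameters, extracts the bundled feature names, applies the bundled
normalizer and predicts; the stability score is
`clamp((ŷ − label_min)/(label_max − label_min), 0, 1)` — a min–max
calibration of the predicted label against the training range, the same
convention used to place species means on a 0–1 scale in the genome
statistics. One model produces both outputs; score is monotone in the
predicted label by construction.

## Genome statistics

C density = count(C) / count(A,C,G,T), case-insensitive, ambiguity codes
excluded from numerator and denominator. iPM = motifs per million
nucleotides with the denominator taken as single-strand assembly length
(all bases, N included) while motifs are counted on both strands without
overlap — "per million nucleotides" most naturally references assembly
size, but the convention is explicit here because published densities are
sensitive to it. Records are scanned one at a time (motifs never span
records), so memory stays bounded by the largest record, not the genome.
Relative scores across a genome set are min–max normalized means; if all
means coincide they are defined as 0.5 with a warning.

## Synthetic data: what it does and does not emulate

The generator produces (i) i.i.d. backgrounds at a target GC content
(default 0.42) certified motif-free on both strands — accidental
candidates are destroyed by a single tract substitution and re-scanned
until clean — and (ii) motifs drawn uniformly from the constraint grammar,
spiked at random strands/positions with ≥50 nt separation and A/T-only
flanks wider than the maximal loop, so a scan recovers exactly the truth
table. Labelled datasets attach labels that are linear in chosen canonical
features plus Gaussian noise; the default study condition is n=500,
three informative features (mean tract length +0.25/nt, total loop length
−0.02/nt, A fraction +0.8) around an intercept of 6, with noise fixed so
the signal explains 90% of label variance. An optional flag clips labels
to a plausible transition-pH window of 5.5–7.5.

Real genomes are not i.i.d. (repeats, isochores, CpG suppression) and real
transition-pH data are neither linear in these features nor homoscedastic;
passing the recovery tests therefore demonstrates correctness of the
machinery — exact motif arithmetic, honest cross-validation, calibrated
round trips — not biological accuracy of any shipped model. No
experimentally trained default model is included; users supply their own
measurements to train one.

## Numerical choices and degenerate inputs

Ties in placement selection are broken deterministically (leftmost);
KFold shuffling, train/test splitting, estimator seeds and the TPE stream
all derive from the run seed (per-config seeds via CRC32 mixing), so
(data, budget, seed) fully determine the history. R² is undefined for
zero-variance targets and raised as an error; selectors that drop every
feature make the pipeline fail and score −∞. Zero-length inputs yield
empty candidate lists, not errors. Desk-scale problem sizes used by the
test suite and the acceptance script (genomes of 0.2–1 Mb, training sets
of 100–500 sequences, the swift/balanced presets) were chosen so the full
suite runs on one CPU in minutes while still exercising every code path
at the documented study conditions.

## Known limitations

* The detection grammar is structural only — no thermodynamics, no
  G-quadruplex competition on the complementary strand, no chromatin
  context.
* The 33-feature set is sequence-derived; structure-derived or k>2
  k-mer features are out of scope.
* Bundles are portable across installations of this package, but the
  model blob is implementation-specific (tagged joblib pickle), not a
  cross-language model exchange format; the manifest is.
* Tabu search with one evaluation per round is a pragmatic variant;
  with very large portfolios a full-neighbourhood Tabu would explore
  differently (irrelevant at 84 pairs, where exhaustive budgets exist).
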