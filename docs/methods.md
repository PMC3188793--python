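# Methods note

This note records the statistical model implemented by `chipmeta`, the
meaning and defaults of every tunable parameter, what the synthetic data
generator does and does not emulate, the numerical choices made where the
underlying method is under-specified, and the known limitations.

## 1. ChIP-chip meta-analysis

### 1.1 Common grid

Probe-level score tracks from different platforms are mapped to a shared
genomic grid so that pointwise combination is meaningful.

- Grid positions are the multiples of `target_step` (default **7 bp**,
  the finest common platform spacing) covering each track's span; anchoring
  at coordinate 0 makes grids from different tracks align by construction.
- A grid value is obtained by **linear interpolation** between the two
  flanking probes, but only when the flanking-probe gap is at most the
  track's `max_interp_dist` (per-platform: 10 / 50 / 100 bp for 7 / 35 /
  100 bp-resolution arrays). Larger gaps yield missing values (NaN): a
  sparse array is never allowed to invent signal between distant probes.
- Grid points coinciding with a probe take the probe's value exactly.
  Duplicate probe positions in the input are collapsed by averaging.

### 1.2 Robust per-track null

Scores are standardized per track as `Z = (x − μ₀)/σ₀` with

- `μ₀` = median of all finite grid values;
- `σ₀` = 1.4826 × median(|x − μ₀|) computed over the **left** half of the
  distribution only (values ≤ median, reflected about it).

Enrichment produces a heavy right tail; the reflected left-side estimator
ignores it, so genuinely enriched tracks are not penalised by their own
signal. At least 100 finite values are required; a degenerate (zero-spread)
track is an error rather than a silent division by zero.

### 1.3 Weighted Stouffer combination

At every grid point covered by at least `min_datasets` tracks (default
**1**):

    S = Σ_i w_i Z_i / sqrt(Σ_i w_i²)

with per-track weights `w_i` (default all 1). The denominator uses exactly
the tracks present at that point, so `S` is standard normal under the null
for any coverage pattern — this is verified empirically by a
Kolmogorov–Smirnov test in the test suite. The number of contributing
datasets is carried alongside `S` for every point.

### 1.4 Peak calling and sign-flip eFDR

- Threshold: `z₀ = Φ⁻¹(1 − pvalue_cutoff)`, with `pvalue_cutoff` default
  **1e-4**.
- Maximal runs of `S > z₀` are merged when separated by at most
  `merge_gap` bp (default 2 × grid step) and discarded when shorter than
  `min_peak_len` (default 4 × grid step).
- The summit is the leftmost grid point attaining the run maximum; the
  peak p-value is `Φ̄(max S)`.
- Empirical FDR: peaks are re-called on `−S` with identical settings and
  `eFDR = min(1, N_neg / N_pos)`. When no positive peaks exist the eFDR
  is **not defined** and reported as `None` (never 0, which would
  overstate confidence).

## 2. ChIP-seq meta-analysis

### 2.1 Per-library fragment-size model

Sequenced tags are 5' ends; the true binding site lies ≈ `d/2` downstream
(Watson) or upstream (Crick) of the tag, where `d` is the library's mean
fragment length. `d` is estimated per library:

1. Tags are deduplicated to at most `max_dup_per_pos` (default **1**) per
   position and strand.
2. Candidate windows of width 2 × `bandwidth` (default bandwidth
   **300 bp**) are scanned at `bandwidth` steps; windows whose tag count
   corresponds to a fold enrichment between `mfold_lo` and `mfold_hi`
   (defaults **10–30**) over the genome-wide expectation are kept,
   greedily and non-overlapping, best first, up to `max_model_peaks`
   (default **1000**). Fewer than `min_model_peaks` (default **100**)
   aborts model building.
3. Each candidate is re-centred on the midpoint between its Watson and
   Crick tag means; Watson and Crick positional profiles are accumulated
   from the whole library around these midpoints.
4. `d` is the lag maximising the cross-correlation between the smoothed
   (21-point moving average) Watson and Crick profiles. Re-centring plus
   cross-correlation proved markedly more accurate than the difference of
   profile modes, especially for fragments larger than the window step.
5. An estimate below `min_d` (default **50 bp**) is rejected and replaced
   by `default_d` (**100 bp**), matching common sonication protocols.

Tags are then shifted 3'-ward by `d // 2` (floor; Crick positions clipped
at 0). Shifting each library with **its own** `d` before pooling is the
core of the meta-analysis: it aligns evidence from libraries prepared with
different fragment sizes onto the binding site itself.

### 2.2 Pooled dynamic-Poisson scan

Shifted libraries are pooled with per-source depth bookkeeping. The genome
is scanned in windows of width `w₀` = `scan_window` if set, otherwise the
largest per-library `d` (fallback `default_d`), at a step of `w₀/2`.
Windows with Poisson p-value below `seed_pvalue` (default **1e-3**)
against the genome-wide rate `λ_bg = depth × w₀ / genome_size` are kept,
overlapping seeds are merged, and each merged region is re-scored against
a **dynamic λ**:

    λ_local = max(λ_bg, λ_1k, λ_5k, λ_10k)

where the local rates come from the control (depth-scaled to the ChIP
library) when a control is provided, and from the ChIP data itself —
dropping the 1 kb term, which would be contaminated by the peak — when
not. Final peaks satisfy `pvalue_cutoff` (default **1e-5**); the reported
score is `−10 log₁₀ p`. `genome_size` defaults to **2.7e9** (mappable
human genome); synthetic analyses must pass their own genome length.

The summit is the maximum of the shifted-tag pileup smoothed with an
odd-width triangular kernel of width ≈ `w₀/2` (leftmost position on
ties). Poisson upper tails are computed as `P(X ≥ k) = gammainc(k, λ)`
(the regularized lower incomplete gamma function), which is exact and
stable; the test suite checks it against direct log-space summation to
a relative error of 1e-12.

### 2.3 Sample-swap eFDR

The scan is repeated with ChIP and control exchanged;
`eFDR = min(1, N_swap / N_chip)`, and `None` when `N_chip = 0`. On two
identical libraries the construction is exactly symmetric and the eFDR
equals 1 by arithmetic, which the tests verify.

### 2.4 Merge-first baseline

`merged_baseline` pools the **raw** libraries, fits a single fragment-size
model to the mixture, and proceeds as above. It is deliberately included
as the comparator that per-library modeling is designed to beat: when
libraries differ in `d`, the single mixture model centres tags of both
libraries incorrectly and summit accuracy degrades, while the per-library
pipeline is unaffected.

## 3. Baselines and evaluation

- **Majority vote**: genomic regions covered by more than half of the
  per-dataset peak lists. **Intersection**: regions covered by all of
  them. Both are computed by an event-sweep over flattened per-list
  coverage, so overlapping peaks within one list count once.
- **ROC/AUC**: candidates are fixed-width tiles (default 500 bp) ranked by
  their best composite score; a tile is a true positive if it overlaps a
  truth region by ≥ 1 bp; the TPR counts *distinct* truth regions
  recovered; AUC by trapezoid. Unranked (binary) region sets get a
  single-operating-point AUC: `0.5·TPR·FPR + 0.5·(TPR+1)(1−FPR)`,
  evaluated on the same tile universe so numbers are comparable.
- **Summit accuracy**: cumulative fraction of the top-N peaks whose summit
  lies within a tolerance (50 bp in all experiments) of a planted site.

## 4. Synthetic data: what it emulates, and what it does not

### 4.1 Spike-in tracks (ChIP-chip)

Three virtual platforms probe a `genome_len` (default **2 Mb**) genome at
7 / 35 / 100 bp spacing. `n_regions` (default **100**) non-overlapping
regions with lengths N(`mean_len` = 497, sd = `mean_len`/5, floor 100 bp)
receive a per-region uniform fold shift in `fold_range` (default
**2.0–6.0**, in noise-sd units). Probe noise is Student-t with
`noise_df` = **5** — deliberately heavy-tailed, to stress the robust null
and to make the sign-flip eFDR informative — and each probe drops out
independently with probability **0.02**.

Not emulated: probe GC/affinity bias, spatial autocorrelation of array
noise, dye effects, copy-number variation. Region placement is uniform,
not promoter-biased.

### 4.2 Tag libraries (ChIP-seq)

`n_sites` (default **2000**) point binding sites on a `genome_len`
(default **20 Mb**) genome. Each site emits Poisson(`tags_per_site`/2)
tags per strand at `site ∓ d/2 + N(0, d/4)` — the bimodal strand pattern
that the fragment-size model exploits. Uniform background tags are added
at `bg_rate` (default **0.002** per bp, both strands pooled), and a
control library of exactly matched depth is drawn uniformly. `d/4 < 1`
(i.e. `d < 4`) is rejected as degenerate.

Not emulated: mappability gaps, PCR duplication bursts, chromatin-
accessibility background structure, fragment-length *distributions*
(a single `d` per library), closely spaced or overlapping sites.

`make_delta_d_pair(library, delta_d, seed)` splits a library into two
random halves and shifts every tag of one half 5'-ward by `delta_d // 2`,
which increases that half's *effective* fragment size by `delta_d` while
leaving tag counts, strand composition and binding sites untouched. The
parameter is the fragment-size **difference** between the resulting pair,
not the per-tag shift; this convention is asserted by a test that
re-estimates `d` on both halves.

## 5. Numerical and design choices

- All coordinates are 0-based half-open internally; WIG input is 1-based
  per the format. BED peak output keeps coordinates, name, score and
  summit; the tabular dialect round-trips every peak field.
- Peaks with undefined p-value/eFDR carry NaN / `None`, never sentinel
  zeros.
- Ties in summits and in candidate ranking break to the leftmost /
  first-seen element, making every pipeline fully deterministic.
- eFDR values are clipped to [0, 1]; a ratio with a zero denominator is
  `None` ("not defined"), a deliberate distinction from 0.
- Motif analysis uses a 3rd-order Markov background (pseudocount 0.5)
  trained on the analysed sequences, log₂ likelihood-ratio PWM scores on
  both strands, and a significance threshold set as the 1 − 1e-4 quantile
  of scores on sequences sampled from the background chain.
- Problem sizes in tests and in the acceptance script (2 Mb / 10–20 Mb
  genomes, 10²–2·10³ sites) were chosen to keep full runs under a minute
  while leaving all statistical effects far from threshold; they are this
  package's own choice, not an external benchmark.

## 6. Limitations

- The Stouffer composite assumes independent datasets; replicate tracks
  from the same hybridization would need down-weighting the package does
  not attempt.
- Gap-limited interpolation leaves unprobed regions undetectable by
  design; coverage, not the statistic, is the limit for sparse arrays.
- The dynamic-λ scan models background as locally Poisson; it does not
  model broad enrichment domains (histone-mark-like signal), and the
  fixed scan width `w₀` targets point-source factors.
- Fragment-size estimation needs enough high-enrichment candidate windows
  (`min_model_peaks`); very shallow or very noisy libraries fall back to
  `default_d`, and the fallback is reported, not hidden.
- The sign-flip eFDR assumes a symmetric null; asymmetric artifacts
  (e.g. one-sided probe saturation) would bias it downward.
- Empirical FDRs are global per run, not per-peak q-values.
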