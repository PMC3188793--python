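# chipmeta

Model-based meta-analysis of ChIP enrichment experiments. `chipmeta`
combines evidence for protein–DNA binding across *multiple* datasets —
tiling-array ChIP-chip tracks from different array platforms, or ChIP-seq
tag libraries from different labs — into a single ranked peak list, instead
of the common but lossy practice of voting or intersecting per-dataset peak
calls, or naively merging raw data that was generated under different
experimental conditions.

## The problem

Different tiling-array platforms probe the genome at different resolutions
(a few bp up to ~100 bp spacing) and produce scores on incomparable scales.
Different ChIP-seq libraries for the same factor differ in sequencing depth
and, critically, in mean DNA **fragment size** `d`: a 5'-sequenced tag sits
roughly `d/2` away from the true binding site, on a strand-dependent side.
Pooling raw data across such datasets smears the evidence; set-level
combination of per-dataset peak lists throws away the scores and discards
regions that fall just below threshold in any one dataset.

`chipmeta` instead models each dataset on its own terms and combines at the
level of *calibrated statistics*:

**ChIP-chip.** Each probe-level score track is linearly interpolated onto a
common genomic grid (gap-limited, so low-resolution arrays never hallucinate
signal across large probe gaps). Each track is standardized against a robust
null fitted to its own score distribution — median for the center and a
reflected left-side median absolute deviation for the spread, so the
enriched right tail does not inflate the null. The per-dataset z-scores
`Z_i` are then combined pointwise with a weighted Stouffer statistic

    S = Σ_i w_i Z_i / sqrt(Σ_i w_i²)

which is again standard normal under the null, regardless of how many
datasets cover a given position. Peaks are maximal runs of `S` above the
threshold implied by the p-value cutoff, merged across small gaps, with a
sign-flip empirical FDR (peaks called on `−S` divided by peaks called on
`S`).

**ChIP-seq.** For every library separately, the fragment size `d` is
estimated from the cross-correlation of smoothed Watson/Crick tag profiles
around high-enrichment candidate windows; tags are then shifted 3'-ward by
`d/2`. Only after this per-library correction are the libraries pooled
(with depth bookkeeping) and scanned with a dynamic Poisson background:
the rate at each candidate window is the maximum of the genome-wide rate
and local rates estimated in 1 kb / 5 kb / 10 kb windows (from the control
when available, otherwise from the ChIP data itself, dropping the 1 kb
term). A sample-swap empirical FDR (control vs. ChIP) accompanies the peak
list, and peak summits are located on the smoothed shifted-tag pileup.

The package also ships the naive comparators (majority vote, intersection,
merge-first pooling), a synthetic data generator with ground truth for both
assay types, window-level ROC/AUC and summit-accuracy evaluation, and a
PWM/Markov-background motif-occurrence evaluator for assessing peak lists
against an expected binding motif.

## Worked example

Everything below is deterministic and runs in seconds. First, a three-
platform ChIP-chip meta-analysis on synthetic spike-in tracks (platforms at
7 bp, 35 bp and 100 bp resolution, 100 true enriched regions):

```python
import chipmeta as cm

design = cm.SpikeInDesign(seed=12)          # 100 regions in 2 Mb, 3 platforms
tracks, truth = cm.make_spikein_tracks(design)

peaks, efdr, composite = cm.chipchip_pipeline(
    tracks, cm.ChipChipConfig(pvalue_cutoff=1e-6)
)
print(len(peaks), efdr)
top = peaks[0]
print(top.chrom, top.start, top.end, top.summit, round(top.score, 1), top.n_datasets)
hits = sum(1 for p in peaks
           if any(s < p.summit < e for _, s, e in truth.intervals))
print(hits, "of", len(peaks), "summits inside true regions")
```

Output:

```
150 0.14666666666666667
chr1 711711 712306 711802 15.3 3
139 of 150 summits inside true regions
```

Next, a single ChIP-seq library with true fragment size 146 bp, analysed
against a matched control:

```python
d2 = cm.SeqLibraryDesign(n_sites=300, tags_per_site=40, d=146,
                         genome_len=5_000_000, seed=12)
chip, control, sites = cm.make_seq_library(d2)

cfg = cm.ChipSeqConfig(genome_size=d2.genome_len)
peaks, efdr, per_d = cm.chipseq_pipeline([chip], [control], cfg)
print(per_d, len(peaks), efdr)
print(round(cm.summit_accuracy(peaks[:200], sites, 50)[-1], 3))
```

Output:

```
{'synthetic_chip': 147} 300 0.0
1.0
```

The estimated fragment size is 147 bp against a true 146 bp; all 300
planted sites are recovered at zero empirical FDR, and every one of the
top-200 peak summits lands within 50 bp of a true site.

The same analyses are available from the command line:

```sh
chipmeta simulate spikein --n-regions 100 --genome-len 2000000 --seed 12 --output-dir sim
chipmeta chip --track sim/platform_0.wig:p0:7:10 \
              --track sim/platform_1.wig:p1:35:50 \
              --track sim/platform_2.wig:p2:100:100 \
              --pvalue 1e-6 --output-dir out
chipmeta seq --chip chip.bed --control control.bed --gsize 5000000 --output-dir out_seq
```

Each run writes a peak table plus a JSON summary containing the package
version, seed and a hash of the effective configuration.

## Layout

| Path | Contents |
| --- | --- |
| `src/chipmeta/track_io.py` | WIG/bedGraph, BED tag, peak, FASTA and PWM I/O |
| `src/chipmeta/chipchip.py` | gridding, robust nulls, Stouffer combination, sign-flip eFDR |
| `src/chipmeta/chipseq.py` | fragment-size model, tag shifting, pooled Poisson scan, swap eFDR |
| `src/chipmeta/baselines.py` | vote/intersection combiners, ROC/AUC, summit accuracy |
| `src/chipmeta/simulate.py` | spike-in track and tag-library generators with ground truth |
| `src/chipmeta/motif.py` | Markov background, PWM scanning, motif-fraction curves |
| `src/chipmeta/cli.py` | `chipmeta` command-line interface |
| `docs/methods.md` | methods note: model, defaults, numerical choices, limitations |
| `scripts/acceptance.py` | end-to-end recomputation of the headline quantities |
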