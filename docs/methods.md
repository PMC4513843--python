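# Methods

## The assay model

A partially randomized ribozyme library is transcribed by T7 RNA polymerase
from a top-strand DNA template carrying the 17-nt promoter
`TAATACGACTCACTATA`; transcription starts at the first base after the
promoter and runs off to the template end (all shipped templates begin GGG
at +1, the standard strong-start context for T7). Each transcript carries k
degenerate positions (variant space 4^k) and either self-cleaves at a fixed
site — retaining the 3' fragment that begins at `cleavage_site` — or stays
full length. Reverse transcription with a condition-barcoded primer and
adapter ligation turn every molecule into the amplicon

```
adapter_t + barcode + revcomp(fragment as DNA) + adapter_b
```

Because the extra 5' leader of an uncleaved molecule is appended (reverse
complemented) *after* the variable window on the sequenced strand, the
variant letters sit at the same read offsets for both statuses; cleavage
status is read from whether the bases past the junction match the
reverse-complemented leader (uncleaved) or the 3' adapter (cleaved). All
coordinates are 0-based, half-open. Degenerate positions must lie at or
downstream of the cleavage site — randomized bases in the leader would be
lost on cleavage — and design validation enforces this.

The three built-in designs use the published library templates. Their
barcodes and adapters are synthetic stand-ins (the original primer/adapter
oligos are not part of the published templates): Illumina-index-style
6-mers at Hamming distance 4 and TruSeq-style 20-nt adapters. The cleavage
sites are approximate reconstructions (the original account marks them only
graphically): a 9–10 nt 5' leader, upstream of all randomized bases, which
is the only property any computation here depends on.

## Classification

Per read, three anchored, substitution-only comparisons:

1. **Demultiplex** — the barcode window at the fixed offset after
   adapter_t is compared to every barcode; the winner must be within
   `max_bc_mismatch` (default 0: the original tolerance is unstated and
   real inter-barcode distances are unknown, so exact matching is the
   conservative default) and strictly closer than every other barcode.
   Ties reject the read.
2. **Library assignment** — the read is scored against each registered
   design's cleaved and uncleaved references with barcode and degenerate
   positions wildcarded; the best design needs ≤ `max_ref_mismatch`
   (default 3) constant-position mismatches and a lead of ≥ `min_margin`
   (default 1) over the runner-up.
3. **Status call** — cleaved vs uncleaved reference for the assigned
   design, same threshold and margin; margin failure yields AMBIGUOUS
   (excluded from counting — this biases neither class), threshold failure
   `ref_mismatch`. The variant is read back from the wildcarded offsets,
   complemented into RNA sense (5'→3', letters ACGU, matching the
   enumeration order); any non-ACGT base there rejects the read as
   `bad_variant`.

A read must cover at least `min_margin` of the positions at which the two
references differ, else it is rejected `too_short`; a `read_length`
truncation option emulates fixed-cycle runs. An orientation flag
reverse-complements reads whose run sequenced the opposite strand; the
original run geometry is unstated, so both orientations are supported and
classification is invariant under consistent flipping (tested).

No indel alignment (reads with indels fall into `ref_mismatch`) and no use
of base qualities — the counting statistic never used them. Known bias: a
substitution error *at* a degenerate position silently moves a read to a
neighboring variant; it is undetectable in principle, enters at rate
≈ k·ε, and is covered by the simulator-based recovery bounds below.

## Statistics

- Fraction cleaved `f = c/(c+u)` is reported raw (never smoothed); zero
  depth gives NaN plus a `low_depth` flag, never an exception.
- The on/off ratio uses Jeffreys pseudo-counts, `f̃ = (c+0.5)/(c+u+1)`,
  in both conditions, so a variant with zero cleaved −ligand reads still
  has a finite, positive fold change. The pseudo-count lives only inside
  the ratio so reported fractions stay exact quotients.
- The phenotype gate is strict: `f₊ > 0.30` and `ratio > 3.0` (defaults;
  whether the original thresholds were inclusive is unstated — strict was
  chosen and is documented here). Tightening either threshold can only
  shrink the pass set (tested property).
- Rankings sort by descending fraction with lexicographic tie-break, for
  determinism. Pattern matching follows IUPAC semantics with U≡T.
  Profile-vs-profile comparison is OLS of y on x plus squared Pearson
  correlation on untransformed fractions (matching how such assays are
  validated against gel measurements); zero variance in x yields NaN.
- The minimum-depth flag defaults to 50 reads per variant-condition; it
  marks but never removes variants (no depth threshold was stated for the
  original data, where all variants were well covered).
- Sequencing capacity: `variants = floor(total_reads/mean_depth)`,
  `equivalent bases = round(log4 variants)` (nearest integer, so 4×10⁶
  variants ↦ "about 11" bases).

## Simulator: what it does and does not establish

The generator draws a true fraction per (condition, variant) — uniform,
beta, or an explicit table — fixed or Poisson depth, cleaved counts
Binomial(depth, f), builds each read with the same amplicon constructor the
classifier is tested against, applies iid substitutions at rate ε (uniform
over the three alternative bases), optionally truncates reads, and shuffles
read order so the classifier cannot exploit grouping. Output is
byte-deterministic per seed; a manifest records truth and parameters.
Default depth 1000 and ε = 0.001 correspond to the real assay's regime
(reported per-variant coverage ≈ 1100–5900 reads; ~0.1% is a typical
per-base substitution rate for the platform used).

Not modeled: PCR amplification bias, chimeras, RT dropout, indels, per-cycle
error profiles, quality-score structure. A green recovery test therefore
establishes that counting, classification and bookkeeping are correct under
binomial sampling plus substitution noise — not that the wet-lab steps are
bias-free. Consistent with that, the replicate-concordance check (two
independent simulated replicates, depth 1000, r² ≥ 0.95) sits deliberately
above the real assay's replicate R² of 0.90, which includes biochemical
noise no desk simulation reproduces.

## Numerical and design choices

- Recovery bounds: at depth 1000 the worst-case binomial SD of f̂ is
  0.0158, giving the tested envelope max|f̂−f| ≤ 0.06 (≈3.8σ) and
  MAE ≤ 0.02 across 256 variants.
- The throughput requirement (a full 1024-variant, ~2M-read twister run
  classifying within 15 minutes) is verified on a 200k-read simulation and
  extrapolated linearly; classification cost is strictly per read.
- Variant strings are written 5'→3' in RNA letters, matching the
  conventional naming of these libraries (wild-type twister window
  `GUUAC`).
- Transcription yield, DNase digestion, RT and ligation efficiencies are
  absorbed into the depth parameter (ligation was near-quantitative in the
  original protocol).
- Kinetic rate-constant extraction from time-course barcodes is out of
  scope; arbitrary condition labels are representable, but no kinetics
  model is implemented. No multiple-testing machinery: the analyses are
  descriptive.

## Limitations

- The shipped cleavage-site offsets and barcode/adapter sequences are
  synthetic/approximate (see above); users reproducing a real run must
  supply their own design YAML with the true oligos.
- Single-end, substitution-only matching: indel-rich platforms would need
  an alignment-based classifier.
- The benchmark activity table covers only the 20 published variants; full
  per-variant activity landscapes of the real libraries are not
  redistributable here and are emulated by the simulator instead.
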