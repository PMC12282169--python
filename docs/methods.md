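# Methods

## Problem and model

Total RNA extracted from gut-microbiome samples is dominated by microbial
ribosomal RNA: without depletion, the large majority of sequencing reads
map to SSU/LSU rRNA transcripts and are wasted for metatranscriptome
(MetaT) analysis. Commercial depletion probe pools are designed against
human-derived communities and perform inconsistently on other hosts.
ribotile implements an abundance-guided, taxonomically neutral way to
design supplementary depletion probes directly from sequencing data:
rather than enumerating the taxa present, it finds the reference regions
where rRNA reads actually pile up and tiles antisense oligos across them.

The pipeline, end to end:

1. **Triage.** Reads shorter than `min_length` (default 50 nt) or with
   mean Phred below `min_mean_quality` (default Q20) are dropped. The
   survivors are binned into `rRNA` / `host` / `retained` by canonical
   k-mer containment (default k = 21) against reference indexes checked
   in priority order; a read is assigned the first label whose index
   contains at least `min_hit_fraction` (default 0.25) of the read's
   k-mers. "Below Q20" is deliberately interpreted as a read-level mean
   (not per-base trimming), and the k-mer containment classifier is a
   transparent stand-in for a seed-and-extend aligner: both choices are
   the simplest contracts that preserve the pipeline's information flow
   and are exactly testable against brute-force oracles.
2. **Learning-set selection.** Samples whose rRNA read fraction strictly
   exceeds `learning_set_min_rrna_frac` (default 0.30) form the learning
   set for probe design.
3. **Coverage and abundant regions.** rRNA-binned reads are piled up
   per reference; maximal runs of positions with depth strictly greater
   than `coverage_min` (default 500x) become abundant regions. Runs
   separated by at most `merge_gap` positions (default 0) are bridged,
   and merged runs shorter than `min_region_length` (default 50 nt, one
   probe) are discarded. Each region carries its sense-strand sequence
   and its median depth; median (an order statistic robust to edge
   ramps) is the ranking statistic.
4. **Ranking and pooling.** Each sample's regions are ranked by median
   depth (ties broken by reference id, then start coordinate) and the
   top `top_n` are kept; selections are concatenated across samples with
   provenance.
5. **Redundancy filtering.** Pairwise identity is computed by global
   alignment (match +1, mismatch -1, gap -1, end gaps penalised;
   identity = matched columns / alignment columns). Pairs at or above
   `identity_threshold` (default 0.80) are edges of a similarity graph;
   exactly one region per connected component is retained, chosen
   uniformly at random under an explicit seed recorded in the output.
   Using connected components rather than greedy pair-at-a-time removal
   makes the retained count independent of input order and exactly equal
   to the component count, which keeps the behaviour provable. A
   conservative Levenshtein-based bound
   (identity <= 1 - d/(|a|+|b|), computed with edlib) screens out pairs
   that cannot reach the threshold before the full alignment is run;
   because the bound is provably an over-estimate of any alignment's
   identity, the screen never changes the graph.
6. **Tiling.** Each retained region is tiled left-to-right from its
   5' end with `probe_length`-nt antisense probes (reverse complements of
   the sense windows) at stride `probe_length + gap`; a trailing stretch
   shorter than one probe is not tiled, and no end-anchored final probe
   is added. Probe count per region is therefore
   `floor((L - probe_length)/(probe_length + gap)) + 1` for L >= probe
   length, else 0.
7. **The design matrix.** `design_matrix` sweeps `top_n` over
   {20, 25, 30, 50} and `gap` over {25, 30, ..., 50} with a shared seed,
   reporting the probe count per cell; pools are named `<top_n><gap>`
   (the "5050" and "2025" pools are the two corners of practical
   interest). Counts are non-increasing in gap and non-decreasing in
   top_n by construction. Pools larger than `max_pool_size` (default
   384, a synthesis-economics limit) trigger a warning, not an error.

## In-silico evaluation

Depletion is modelled as interval overlap: a read is removed when any of
its alignment intervals overlaps any probe target by at least
`min_overlap` bases (default 25, half a probe). No melting-temperature,
mismatch-tolerance or enzyme-kinetics model is attempted; the surrogate
is monotone in the probe set and checkable against an all-pairs scan,
which is what the tests do. Reported alongside: per-category read counts
before/after, the retained (non-rRNA, non-host) fraction, Shannon
diversity H = -sum p_i ln p_i of taxon profiles (natural log — stated
here because the base changes the numbers), total-sum scaling (each
sample column normalised to 1), and Spearman/Pearson profile
correlations (average ranks for ties).

`probe_target_coverage` measures design recovery: the fraction of
ground-truth abundant bases lying inside the union of probe targets,
with gaps up to the design spacing bridged (a fragment shorter than the
read length that starts between two adjacent probes still overlaps one
by at least the minimum overlap, so bridged spans are effectively
depleted territory).

## Synthetic communities

The generator emulates the situation the method assumes: a skewed
community whose reads are mostly rRNA. One sample is defined by

- abundant rRNA references (default 3, ~1.5 kb, SSU scale) with
  geometric abundances (consecutive ratio `abundance_skew`, default 1.3),
  shared across samples so equivalent regions exist to combine;
- rare rRNA references (default 40) sharing `rare_mass` (default 5%) of
  the rRNA mass, partially sample-private (`shared_taxa_fraction`);
- optional host and mRNA references carrying the non-rRNA mass;
- per-sample rRNA read fraction drawn uniformly in `rrna_frac_range`
  (default 0.32-0.55, the regime where supplementary design is worth
  doing; 0.97 reproduces the undepleted regime).

Reads have uniform start positions, i.i.d. substitution errors, and
constant quality strings; a configurable fraction is constructed to fail
the length-50/Q20 filter (flagged in the truth so filter exactness is
checkable). Emitted alignments are the true source intervals — a
perfect-aligner surrogate, since alignment itself is out of scope. Not
modelled: indels, paired ends, PCR duplicates, and the real
secondary-structure-driven coverage unevenness of rRNA (which has no
stated quantitative form); passing tests therefore demonstrate the
pipeline's correctness and its recovery behaviour under uniform
coverage, not performance on real libraries.

The standard study conditions used by the test suite and the acceptance
script are 8 samples (7 learning + 1 held-out) of 150,000 reads x 150 nt
each, regions extracted at >500x. With these sizes the weakest abundant
reference's expected interior depth (~900x at the low end of the rRNA
range) clears the 500x threshold by well over 3 standard deviations,
while rare references (~5x) stay far below it, so abundant-region
recovery is a sharp property rather than a coin flip. Closed-form truth
intervals use the exact finite-size expectation
`n_reads * abundance * read_length / (L - read_length + 1)` with the
linear coverage ramps at reference ends.

## Numerical and degenerate-input conventions

- All intervals are 0-based half-open; SAM is converted at the parser.
- FASTQ is Phred+33 only; a heuristic (minimum quality >= 26 with
  maximum > 45) rejects likely Phred+64 files instead of mis-decoding.
- Depth thresholds are strict (`>`), matching the ">500x" convention.
- Median of an even-length window is the mean of the two central values.
- Empty samples produce `fractions = None`, never NaNs; empty probe sets
  and empty region lists are warnings, not errors.
- k-mers containing non-ACGT characters are skipped on both the index
  and the read side; reads shorter than k fall through to `retained`.
- Dedup ties and random draws: components are visited in order of their
  first member and sampled with one `random.Random(seed)`, so identical
  inputs + seed give byte-identical outputs.
- Tiling windows that would collide (two retained regions tiling the
  same probe window) get a numeric id suffix to keep probe ids unique.

## Known limitations

- The identity of an optimal global alignment is not always unique when
  co-optimal alignments with different gap placements exist; the pinned
  scoring makes the *score* unique, and the redundancy decision is made
  on the computed identity of one optimal alignment (Biopython's). Tests
  exercise the regime (planted substitutions) where the identity is
  unambiguous.
- The hybridisation surrogate ignores probe thermodynamics, so absolute
  depletion percentages on synthetic data should not be read as wet-lab
  predictions; only orderings and recovery properties transfer.
- The k-mer classifier has no notion of sequence similarity below exact
  k-mer sharing; highly diverged rRNA would need a smaller k or a real
  aligner upstream.
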