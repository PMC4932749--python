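# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that keep results reproducible.

## Coordinates and strands

All internal coordinates are 0-based half-open on the forward reference
strand, with an explicit strand attribute (BED convention). GTF input
(1-based inclusive) is converted on read and back on write; the conversion
is an exact bijection. iCLIP is strand-specific, so overlap tests,
deduplication, peak calling and motif scanning are strand-aware throughout;
"transcript orientation" below means 5′→3′ along the annotated gene.

## Read model and preprocessing

Reads carry a 9-nt 5′ barcode `RRRIIIIRR`: the three R-positions before and
two after the 4-nt sample identifier are concatenated *in read order* into a
5-bp random tag (UMI), appended to the read name as `#TAG` so it survives
any aligner; the sample name travels as a `sample/` prefix. Order of
operations is barcode parse → quality trim → adapter trim → length filter
(≥ 20 nt), matching the protocol's processing order.

Choices the protocol leaves open, recorded as package defaults and exposed
in `PipelineConfig`:

- **Quality trimming** uses the standard running-sum rule from the 3′ end at
  Q20 (`quality_threshold`); no specific algorithm or threshold is dictated
  by the protocol.
- **Adapter trimming** allows ≤ 1 substitution (`adapter_max_mismatch`), no
  indels, and requires a ≥ 3-nt terminal overlap (`adapter_min_overlap`) so
  that 1–2 nt chance matches do not nibble read ends; a full internal
  adapter occurrence truncates from its start.
- **Demultiplexing** requires an exact identifier match: identifiers are
  only 4 nt, so tolerating mismatches would risk cross-sample bleed.

## PCR-duplicate collapsing

Duplicates are detected per (chromosome, strand, 5′ alignment start, sample)
group — the 5′ start rather than the full span, because 3′ trimming makes
fragment ends variable for copies of one molecule. Within a group, tags
within Hamming distance 1 are "considered identical"; we implement this as
connected components of the distance-≤1 graph (transitive), found by
enumerating single-base neighbours. A greedy non-transitive mode
(`transitive=False`) is provided because the identification rule does not by
itself resolve transitivity. The retained representative is the record with
the lexicographically smallest tag (earliest on ties), making output
deterministic.

With 5-nt tags, two *distinct* molecules at one position collide within
distance 1 with probability 16/1024 ≈ 1.6% per pair; the collapse then
(correctly, per the rule) merges them. Exact molecule-count recovery is
therefore only guaranteed where true tags are pairwise well separated, and
the tests assert exactly that.

## Crosslink assignment

Truncated reads: the crosslinked base is the base immediately 5′ of the read
start in transcript orientation — genomic `start − 1` on the + strand,
`end` (the base just past the alignment) on the − strand. The − strand
convention is pinned by a round-trip property against the simulator.
Read-through reads: the crosslink is the deletion position; reads with a
multi-base deletion use the 5′-most deletion position in transcript
orientation. Sites with negative coordinates are skipped and counted.

The read-start diagnostic tiles the genome in 300-nt windows, keeps windows
with ≥ 20 fragments, and reports per window the modal start offset between
the long fragment class (41 ± 1 nt) and the short class (20–35 nt), computed
as the lag maximising the cross-correlation of the two start histograms
(ties broken toward 0). The data are "start-concordant" when the mode of
per-window offsets is 0.

## Peak calling

Each deduplicated crosslink site is extended ±10 nt (21-nt regions);
overlapping same-strand regions merge into candidates. Sites are assigned to
genes over the full pre-mRNA extent (gene span including introns),
per strand; intergenic sites are not tested.

The null model is *superlocal*: the window is the candidate ± 500 nt clipped
to the gene (≈ 1 kb), its total molecule count is redistributed uniformly at
random over the window's positions, and the test statistic is the maximal
21-nt sliding-window molecule count. The candidate's observed statistic is
compared with the permuted maxima; p = (1 + #{perm ≥ observed})/(n + 1), so
p is never 0 and is valid (super-uniform) under the null — the permuted
maximum is taken over the whole window, which is, if anything, conservative.
`n_permutations` defaults to 1000. The permutation loop is *adaptive*
(batches of 100, stopping once 25 exceedances accumulate): small p-values
get full resolution while clearly null candidates stay cheap; the truncated
estimator remains conservative. All draws come from one seeded generator, so
peak lists are bit-reproducible.

BH adjustment is applied transcriptome-wide across all candidates of the run
(the alternative, per-gene adjustment, is not used); the significant set is
FDR ≤ 0.10. No transcriptome-wide global count cutoff is applied. This
module is a documented stand-in for an external peak caller whose internals
are unpublished; no equivalence is claimed.

## Motif analysis

Foreground = peak sequences on the sense strand; background = length-matched
dinucleotide-shuffled copies (non-overlapping doublet permutation — an
approximation to an exact Euler-path shuffle) or uniform-random sequence.
For each k ∈ {6,7,8}, every k-mer's fold enrichment uses 0.5 pseudocounts
per cell, and a one-sided binomial test (background rate as null) is
BH-adjusted within k. The frequency matrix is built from occurrences of the
top k-mer and its 1-mismatch neighbours in the foreground (ungapped); this
replaces an external finder's mismatch merging and multi-length
optimisation, again as a stand-in.

Scoring: `score[i][b] = log2((f[i][b] + ε)/(0.25 + ε))` with ε = 0.001 —
small enough to preserve the printed limits (f = 1 → ≈ 2 bits, f = 0.25 → ≈
0) while avoiding −∞. Scanning reports every window above a bit-score
threshold; U and T are interchangeable; the reverse complement is never
scanned. `variant_effect` is the change in the best window score overlapping
the variant position (alt − ref); negative predicts disruption.

## Splicing quantification

PSI = inclusion/(inclusion + exclusion) per replicate; a condition's PSI is
the mean over quantifiable replicates. ΔPSI = PSI_kd − PSI_ctrl;
log2FC = log2((PSI_kd + 0.01)/(PSI_ctrl + 0.01)) with the 1% pseudoinclusion
applied verbatim. Significance: two-sided Fisher exact test on counts pooled
across replicates per condition, BH across events, threshold FDR < 0.1.
Directionality follows the biology of a splicing repressor: inclusion up on
knockdown ⇒ repressed; down ⇒ activated.

Pooling ignores replicate overdispersion, so the type-I error is controlled
only to the extent replicates are exchangeable binomial draws (true in the
simulator; optimistic for real data). A beta-binomial model is the natural
extension point and is deliberately not the default.

Splice-site strength uses a pluggable scorer. The built-in
`PwmSpliceScorer` trains first-order PWMs on annotated donor (exon −3 …
intron +6) and acceptor (intron −20 … exon +3) windows with 0.5
pseudocounts against a uniform background; it exists to drive the group
comparisons and is *not* a substitute for a maximum-entropy splice model —
any callable mapping a window to a score can be plugged in. Group
comparisons (regulated vs neutral; also GC content of exon and ±100-bp
flanks) use two-sided Wilcoxon rank-sum tests; groups under 3 members are
skipped with a flag.

## Metagene profiles

`genomic_distribution` assigns every site exactly one region class with
precedence CDS > UTR > intron > intergenic, evaluated on the longest isoform
per gene (the precedence is a package convention, configurable in
principle); densities are count/kb of the class's total length.
`metagene_profile` maps sites onto 100-nt unscaled flanks (1 nt/bin) around
a body scaled to `body_bins` (default 100); each site counts for the first
region whose extended span contains it, so flank overlaps are not double
counted. Densities are per million input sites; 95% bands come from a
percentile bootstrap over *regions* (not sites), so correlated sites within
one region do not shrink the band.

## SSO target selection

Distance is measured in transcript orientation from the first intronic base
(donor +1) to the peak's nearest edge — a peak starting at the 11th intronic
base is "11 nt downstream". Peaks with distance in [10, 40] (inclusive at
both ends) of a repressed cassette exon's donor qualify; pseudoexons enter
as user-supplied intervals. Candidates are ranked by
(Σ motif-hit scores in the 10–40 window) × log2(1 + peak height) — a
labelled heuristic, since no quantitative ranking is prescribed; the motif
threshold defaults to half the matrix maximum. The proposed oligo is the
reverse complement (RNA alphabet) of the shortest 18–25-nt window covering
the window's motif hits, padded symmetrically to 18 nt, clipped to never
overlap the donor region (exon −3 … intron +6); spans over 25 nt emit a
maximal-coverage oligo with a warning.

## Synthetic data: what it emulates and what it does not

The generator builds one chromosome of `n_genes` multi-exon genes on
alternating strands in i.i.d. uniform-ACGT background (each base 0.25), with
two transcripts per gene where cassette exons exist (full and skipping
isoforms) and a CDS spanning mid-first to mid-last exon so UTR classes are
populated. Crosslink sites sit on jittered ~12-nt slots inside genes
(near-uniform, but guaranteeing implanted motifs never overlap); the motif
(default UAGGGA) is implanted at `motif_implant_rate` (default 0.6) of
sites, on the gene's sense strand.

Reads follow the truncation/read-through mixture. The protocol asserts both
signal types exist but quantifies neither, so the defaults —
`truncation_fraction` 0.85, read-through otherwise with a uniform 1–2-nt
deletion — were chosen once so that both code paths are exercised, and are
config values, not measured quantities. Each site hosts
1 + Poisson(`molecules_per_site_mean` − 1) molecules; each molecule is
sequenced 1 + Poisson(`pcr_duplication_mean` = 3) times with per-base tag
substitution errors at `tag_error_rate` = 0.01. Fragment lengths are uniform
on 20–41 nt; shorter fragments read through into the adapter, exercising
adapter trimming. Qualities are constant high (a flag degrades 3′ ends to
exercise quality trimming). True alignments are emitted directly so tests
need no aligner; an exact-substring aligner is included only for error-free
end-to-end smoke tests. Junction counts are Binomial(depth, PSI) per
replicate, independent across replicates — exactly the exchangeability the
Fisher stand-in assumes.

Not emulated: empirical base-quality and error profiles, fragment-length
distributions, repetitive or biased-composition genomes, multi-chromosome
structure, crosslinking sequence preference beyond the implanted motif, and
overdispersed junction counts. Passing tests therefore demonstrate the
*algorithms* invert the stated models; they do not certify performance on
real libraries, where duplicate structure, mappability and overdispersion
are harsher.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small instances —
10–100 genes, ~10⁴ reads, 200–1000 permutations, 10–20 seeds per
calibration — chosen as the smallest sizes at which the measured rates
(recovery ≥ 99%, null FDP ≤ 0.15, motif recovery 19/20, power ≥ 0.8) are
stable across seeds. Every stochastic component draws from
`numpy.random.default_rng` seeded from a single integer, so all outputs,
including CLI files, are byte-reproducible.
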