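# Methods

## Scope and model

`gliascan` quantifies celiac-disease (CD) epitopes in RNA amplicons of the
alpha-gliadin N-terminal repetitive domain. The measurement model is
count-based: every amplicon read is one observation of one transcript; a
merged, demultiplexed read reduced to its coding core and translated either
carries an epitope window or it does not, and per-line epitope abundance is
the cluster-weighted sum of window occurrences. The method assumes
orientation-fixed amplicons (the degenerate primers bind unique motifs, so
all sequences are handled on the forward strand), a fixed read layout
(8 nt barcode, forward primer, signal-peptide remainder, variable core,
reverse-primer complement), and substitution-dominated sequencing error
(no indel model; an indel would shift the reading frame and the affected
read would fail translation-level matching rather than create false
counts).

## Pipeline stages and parameters

* **Quality trimming** — sliding window, size 4, mean Phred ≥ 15, minimum
  surviving length 36 nt. These are the common defaults of window-based
  trimmers; the trimming stage exists for real data and is inert on the
  synthetic reads (constant high quality).
* **Pair merging** — R2 is reverse-complemented and the pair is joined at
  the overlap with the best alignment score (matches − 2·mismatches),
  subject to a minimum overlap of 10 nt and a mismatch fraction ≤ 0.25;
  ties prefer the longer overlap; disagreeing bases take the
  higher-quality read (ties favour R1). A score was chosen over raw
  overlap identity deliberately: the 33-mer coding region is 21 nt
  periodic over 63 nt and glutamine runs are 3 nt periodic, so when an
  error lands in a short true overlap, a shorter error-free overlap at a
  repeat shift can reach identity 1.0 and win, silently deleting one
  repeat unit from the merged sequence. Under the score, beating a true
  overlap requires implausibly many errors.
* **Demultiplexing** — exact 8-mer barcode prefix match by default
  (`--barcode-mismatch 1` is supported and requires all barcode pairs to be
  ≥ 2 mismatches apart, enforced at load). Reads whose barcode cannot be
  assigned uniquely are counted as unassigned, never guessed.
* **Strip to CDS** — the forward primer is located IUPAC-aware with ≤ 1
  mismatch (expected offset first, full scan as fallback), the reverse
  primer complement likewise at the 3' end; barcode, primers and the fixed
  42 nt signal-peptide remainder are excised and the remaining core must
  fall in the configurable 192–432 nt window. Coordinates are 0-based,
  half-open throughout.
* **Translation and pseudogene filter** — standard genetic code, frame 0,
  3' remainders trimmed; any protein containing `*` is discarded and
  counted, mirroring the pseudogene fraction of the alpha-gliadin family.
* **Clustering** — exact deduplication of identical proteins. At 100 %
  identity over an identical amplified region this coincides with
  greedy-incremental clustering tools; sequences of different lengths are
  never merged. Clusters need ≥ 20 members (`--min-members`) to enter
  epitope analysis; descriptions of this filter vary between "more than 20"
  and "at least 20", and the configurable ≥ 20 was chosen. Ranking ties break
  lexicographically on the representative for reproducibility.
* **Epitope scanning** — every window of every catalogued epitope length is
  Hamming-compared to every scannable catalogue entry of that length;
  windows within `max_mismatch` (default 1, maximum 2) are counted, and a
  window matching several entries is attributed to the minimum-mismatch
  entry (exact match first, catalogue order on remaining ties), so a
  window is never double-counted as canonical *and* variant. Occurrences
  are positional: overlapping copies count separately, which is what makes
  the intact 33-mer contribute 1× α1a + 2× α1b + 3× α2. The one
  catalogued peptide containing a literal `*` is excluded from scanning;
  its '*' has no amino-acid meaning and collides with the stop-codon
  convention.
* **Normalization** — `normalized = raw × 10⁶ / depth` with
  `depth(line)` = retained coding sequences after all filters, i.e. the
  member sum of the line's thresholded clusters. With this choice reads
  that drop out of counting (sequencing error, threshold) leave numerator
  and denominator together, so normalized values track per-read epitope
  frequencies; at error 0 the depth equals the summed template abundances
  exactly. log2 values use a pseudocount of 1 on the per-million scale.
* **Toxicity** — per line, the normalized counts of classes T / RT / \*T
  are summed and weighted 3 / 2 / 1; NT, \*NT and UNK rows weigh 0 (the
  ubiquitous but non-toxic α3 variant `FPPQQPYPQ` therefore never inflates
  a line). The top line defines 100 % and relative percentages are
  reported at one decimal. An all-zero score vector is a hard error (no
  reference line exists).
* **Consensus and tree** — representatives of the top 10 clusters are
  center-star aligned (global pairwise alignment, match 1 / mismatch 0 /
  linear gap −1 — adequate for near-identical amplicon cores), and the
  cluster-size-weighted per-column majority gives the consensus (residue
  ties alphabetical; gap-majority columns drop from the string but stay in
  the frequency table). Line consensuses are aligned the same way;
  pairwise p-distances (differing columns / compared columns, pairwise gap
  deletion) feed neighbor joining; negative branch-length estimates are
  clamped to zero. Bootstrap support is the percentage of
  column-resampled replicates containing each split (default 1000
  replicates, seed required and recorded). On synthetic data lines
  simulated with similar epitope loads group together; no topology is
  promised for real data, where alignment and distance-model choices are
  tool-dependent.

## The synthetic-data generator

The generator emulates the study design at desk scale: 8 lines × 50
templates, log-normal template abundance (mean 100, σ = 0.4 on the log
scale, clamped at ≥ 20 so every true cluster clears the default
threshold), 250 bp paired reads, i.i.d. per-base substitution errors
(default 0.001, a typical Illumina substitution rate), and a 5 %
pseudogene fraction (the share of stop-codon-containing sequences reported
for this amplicon family). Degenerate primer positions are realized
uniformly at random per template; back-translation uses a fixed
most-frequent-wheat-codon table, shipped as data, for determinism. Every
template records its ground truth as the brute-force scan of its protein
core at the pipeline's mismatch tolerance, and the truth table excludes
pseudogene templates, which the pipeline must also discard.

Epitope content is embedded in a spacer scaffold drawn from residues
(ADEGNSTV) that are rare in the proline/glutamine-rich epitope vocabulary;
scaffolds are re-drawn until a re-scan shows exactly the planned content,
so junction windows never create unintended truth. Two deliberate
restrictions keep recovery well-posed:

* **Margin-safe default plans.** A few catalogued peptides imply a window
  at exactly the scan tolerance of another entry (e.g. the long composite
  `PGQQQPFPPQQPYPQPQPFPSQQPY` contains a 1-mismatch window of the α1b
  variant `PYPQPQLFP`). Occurrences with zero mismatch margin disappear
  with the *first* error that hits them, so their recovery degrades with
  the error rate itself. Default plans therefore draw only from peptides
  whose implied occurrences are all exact; boundary composites remain
  available to `build_template` explicitly.
* **Merge-safe geometry.** Generated cores are capped at 112 aa (336 nt)
  so the true read overlap is ≥ 76 nt — longer than the 63 nt periodic
  stretch of the 33-mer — because shorter overlaps lying inside a repeat
  are *inherently* ambiguous to any overlap-based merger. The observed
  real-data core range extends to 432 nt; such amplicons cannot be merged
  reliably from 2 × 250 nt reads by any tool, which is a property of the
  assay geometry, not of this implementation.

What passing recovery shows, and what it does not: the synthetic reads
exercise degenerate primers, barcodes, overlap merging, pseudogene
filtering, thresholding and mismatch-tolerant counting, but they have
constant base quality, no indels, no chimeric PCR artifacts and no
amplification bias, and the scaffold sequence between epitopes is random
rather than gliadin-like. Recovery on them validates the bookkeeping and
the counting algebra, not robustness to those real-data artifacts.

## Validation design and known limitations

With error 0 the pipeline reproduces the truth table exactly,
cell for cell. Under substitution noise the counting accuracy is assessed
with the prevalence filter lowered to 1: errors make most read-level
protein copies unique, so at the default threshold the surviving clusters
measure the filter's subsampling of clean reads rather than the counting
chain. At 0.5 % per-base error, abundant epitopes (truth ≥ 500 per line)
are recovered within about 2 % on average.

The dominant residual bias is interconversion: catalogued epitopes are
frequently mutual single-mismatch neighbours, so one substitution can turn
a read's copy of one catalogued peptide into an exact copy of another
(α1b → α1a is literally one Y→F change). Such reads genuinely contain the
other epitope — an error-free instrument would report the same window —
and the per-epitope recovery error this induces grows with the error rate
(roughly 2–5 % per row at 0.5 % per-base error, occasionally more for
variant rows with several accessible conversion channels). Class-level
and line-level toxicity sums are much less affected because conversions
largely stay within the family.

Other limitations: demultiplexing is exact-match by default, so the
barcode-error fraction of reads (≈ 4 % at 0.5 % error) is discarded
symmetrically rather than rescued; the depth denominator choice above is
one of several defensible readings of "read depth per line" and is
recorded in every run summary; and the NJ tree on consensus sequences
summarizes only the ten most prevalent clusters per line, so
low-abundance variation does not influence the phylogeny.
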