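# Methods

This note documents the models, parameters and numerical choices behind
`primetx`, and what the synthetic study does and does not establish.

## Coordinate conventions

All internal coordinates are 0-based half-open on the forward strand;
GFF3 input and every emitted table use 1-based inclusive coordinates. A TSS
position is the genomic index of the first transcribed nucleotide; on the
minus strand that is the highest coordinate of the transcript. Promoter
positions are reported relative to the TSS with +1 = TSS, so the −10
element occupies −12..−7.

## TSS calling and normalization

Treated libraries are scaled to 10⁸ reads (`scale_target`). A position is a
true primary position when its scaled read-start count is ≥ 500
(`min_read_starts`) and the start/coverage ratio exceeds 0.5
(`min_start_coverage_ratio`); a position with starts but zero recorded
coverage counts as ratio 1 (real coverage is bounded below by starts; the
guard only matters for degenerate input). Positions are called on
scaled-but-uncorrected tracks; the library-specific correction factor —
the across-library arithmetic-mean primary fraction divided by the
library's own primary fraction — is then applied to read-start counts only.
This normalization is scale-free (multiplying a library's tracks by a
constant leaves its factor unchanged) and compensates for variable
5'-enrichment efficiency. A library with zero counts at primary positions
has no defined factor and is rejected by name. TSSs are reported at
single-nucleotide resolution; a merge window for clustering nearby
positions exists but defaults to off.

The TSS count vector reports the corrected scaled value in *every*
condition, including conditions where the position did not itself pass the
calling criteria; zeroing those entries would bias fold changes toward the
calling threshold.

## TU segmentation

Downstream of each TSS the unit extends while untreated coverage stays
above `min_coverage_fraction` of the running maximum since the TSS, and
terminates after `max_gap` (50 nt) consecutive sub-threshold positions; the
3' end is the last supra-threshold position, capped at `max_tu_length`
(20 kb). The fraction defaults to 0.04: an actuaton retains read-through
into its downstream gene at levels that can fall below 10% of the sRNA
plateau, and a threshold above the smallest biologically admitted
read-through would truncate exactly the units the analysis is designed to
keep intact. The published rule set bounds read-through from below at 0.02
(`min_readthrough`), so 0.04 keeps ordinary background (≲ a few percent)
out while preserving read-through units. When the canonical 10%-rule
behaviour is wanted (e.g., aggressive trimming), the fraction is a
parameter.

A TSS with zero coverage at its own position yields a 1-nt unit flagged
`zero_coverage` rather than an error, so one degenerate track cannot abort
a whole run.

## Classification

Labels follow the g/a/i/n scheme with composites in canonical g, a, i
order. Specific interpretations:

* "covered" for **g** means any sense overlap with the gene body; a minimum
  covered fraction is deliberately not imposed (the alternative is
  documented in the code).
* **i** requires the TSS strictly inside the gene (after the first and
  before the last position), so a TSS on the start codon anchors a
  leaderless gTU, not an iTU.
* The host gene of an internal TSS does not by itself confer **g**; a unit
  that continues into a further gene is g (and i), reproducing the gaiTU
  composite.
* Antisense (**a**) requires ≥ 20 nt overlap with a gene *or another TU*;
  the relation is symmetric by construction.
* Annotated known-sRNA features are markers, not genes: they confer no
  g/a/i label. Otherwise every annotated sRNA unit would be a gTU and the
  distinction the actuaton analysis rests on (a downstream *gene* lacking
  its own gTSS) would collapse.
* TSS classes derive from the unit: i if the TSS is inside a sense gene,
  else g if the unit covers genes, else a, else n.

UTRs are defined for gene-covering units only: utr5 from TSS to the first
member gene's start codon (0 allowed; undefined and flagged when the TSS
is inside that gene), utr3 from the last member gene's stop to the unit's
3' end — the segmented end, since dRNA-seq carries no independent 3'-end
evidence.

## Expression statistics

Fold changes use a pseudocount of 1.0 on the normalized scale, which keeps
all-or-nothing patterns finite; pseudocount 0 is available and then an
infinite UEF is flagged rather than raised. UEF is max/second-max after
pseudocounting; two tied maxima give UEF = 1 (no condition is unique), and
an all-zero vector is flagged undefined.

Significance keeps the published decision rule — |FC| ≥ 2 and
p(|FC| ≥ 2) ≥ 0.95 — but the probability model is this package's own: raw
counts are Poisson with Gamma(1/2, ε→0) (Jeffreys) priors on the rates, so
the posterior rate ratio is a scaled ratio of Gamma variables and the tail
mass P(R ≥ 2 or R ≤ 1/2) has a closed form through the Beta distribution of
G_a/(G_a+G_b), evaluated with the regularized incomplete beta function.
Library-size offsets enter as exposures. The closed form is checked against
a 10⁶-draw Monte Carlo oracle to within 0.01 in the tests.

Ortholog expression profiles are log₂(x+1)-transformed and z-scored per TU
(constant rows map to zero) before a single joint k-means over both
strains' profiles (k = 10, 10 restarts, fixed seed, best inertia). The
same-cluster fraction is the share of ortholog pairs whose members share a
cluster; for unrelated profiles it approaches Σ(cluster share)² ≈ 1/k. The
FC correlation is the squared Pearson correlation of per-strain log₂ fold
changes over all C(10,2) = 45 condition pairs.

## Conservation

* **gTSS**: ortholog co-presence of a gTSS (any position, any condition).
* **aTSS/iTSS**: the position is mapped through the global protein
  alignment of the host gene (BLOSUM62; gap of length k costs 11 + k;
  first optimal alignment kept, fixing tie-breaks) as codon index plus
  within-codon offset; a residue aligned to a gap falls back to the nearest
  aligned column and is flagged inexact. Conservation requires an observed
  partner within 10 nt of the mapped position; matching is greedy nearest,
  one partner per TSS, ties to the lower coordinate. aTSS offsets are
  measured on the sense-gene coordinate frame.
* **nTSS**: the transcript sequence is searched against the partner genome
  with an exact-11-mer seeded, diagonal-clustered, window-refined local
  alignment (match +2, mismatch −3, gap open 5 extend 2; N mismatches
  everything, including N). Problems below 250k DP cells skip seeding and
  run the full local DP, so short-query behaviour is exact. E-values follow
  E = K·m·n·e^(−λS) with ungapped λ and K computed from the scoring scheme
  under uniform base composition via the lattice-case Spitzer series (for
  +2/−3 this yields λ = 0.634, K = 0.408, matching the published constants)
  and n doubled for the two strands. Conserved means best hit with
  E ≤ 10⁻⁵ and single-hit query coverage ≥ 0.5 (aligned query positions /
  query length, query gaps excluded); the hit interval is then checked
  against the partner's TU catalog to separate "conserved as nTU" from
  "conserved but classified differently".

Promoter comparison extracts the 50 nt immediately upstream of a
strain-specific TSS, locates the homologous locus by the same local search
(best hit, E ≤ 10⁻³; otherwise "unalignable"), globally aligns the two
windows and reports every mismatch by position relative to the TSS,
flagging any inside −12..−7.

## Actuaton detection

All numeric bounds here are this package's operational choices; the element
itself is defined qualitatively (abundant discrete sRNA, read-through mRNA,
downstream gene without its own gTSS). A call requires, in order: an
sRNA-like 5' part (nTSS, an annotated known sRNA at the TSS ± 5 nt, or a
gene-covering unit whose drop precedes the first gene — flagged
`utr_derived`); a coverage drop to ≤ 0.5 (`max_drop_ratio`) of the
preceding 20-nt mean within 400 nt of the TSS (`max_srna_len`), refined to
the steepest single-position step; TSS abundance at or above the 75th
percentile of all TSS maxima; a sense member gene starting within 500 nt
after the drop; no *other* unit whose first member gene is that gene (the
operational meaning of "no gTSS of its own" — re-checkable against the TU
table); and a read-through fraction (mean gene-body / mean sRNA-body
coverage) in [0.02, 0.5) — substantial but substoichiometric. Raising the
abundance percentile can only remove calls.

## Synthetic data

The generator emulates the study design: two ~86%-identical genomes with a
shared coordinate system (substitutions only; no rearrangements — a
deliberate simplification that keeps every conserved feature resolvable in
both strains), 120 ortholog genes plus 15 strain-specific genes per strain,
and ten conditions with one treated library each plus a pooled untreated
library. Per strain it plants 100 gTSSs (80 conserved; 20 strain-specific,
4 of which are silenced in the partner by a single transition in the −10
hexamer with the remaining 49 window nucleotides identical), 30 aTSSs and
20 iTSSs inside ortholog genes (12 and 10 conserved, partner offsets
cycling 0..10 nt), 25 free-standing nTSSs (15 conserved in sequence), 8
leaderless genes (start-codon offsets spanning 0..10), and 6 actuatons plus
6 decoys (3 with a strong own-gTSS on the downstream gene, 3 free-standing
sRNAs without read-through). Every planted promoter carries a consensus
TATAAT at −12..−7.

Read starts at a planted TSS follow a negative binomial with mean =
baseline × per-condition multiplier (baseline log-normal, median 300 raw
counts, clipped to [100, 1500]; actuaton sRNAs uniform in [5000, 10000] so
their abundance rank is meaningful; 30% of TSSs receive an extra 5–30×
induction in one condition; dispersion 1/size = 0.2). Dispersion 0 switches
to exact means — the degenerate-noise mode used by the exactness tests.
Treated coverage is 5'-weighted (full level over the first 50 nt, 30%
beyond) so that internal TSSs remain callable against host-gene coverage;
internal planted transcripts are co-terminal with their host unit, because
a 3' end strictly inside the host gene is not recoverable from coverage by
any segmenter. Untreated coverage is the condition-pooled full-length
profile with a 4-fold shoulder and geometric tail (decay length 30 nt) past
the planted 3' end; with the 0.04 segmentation fraction this yields mean
absolute 3'-end errors of ~28 nt, within the 50-nt gap tolerance.
Background positions receive low-rate spurious starts (Poisson, mean 3 raw
counts) paired with ~3-fold excess coverage, so they fail the ratio rule
in expectation and the count rule besides. Library totals are fixed at
2×10⁶ mapped reads, giving a scaled calling threshold of 10 raw reads.

What the simulation does **not** model: sequencing errors and read-level
artifacts, rRNA contamination, structural rearrangements and indels between
strains, transcription termination structure (terminators are hard
boundaries plus decay, not folded hairpins), and library-specific
enrichment-efficiency differences (a per-library knob exists, default 1.0).
Passing tests therefore demonstrate correctness of the decision rules and
robust parameter recovery under count noise, not performance on real
libraries with mapping artifacts or strain rearrangements.

Problem sizes throughout (200 kb genomes, ~205 TSSs per strain, ten
conditions) are the package's default study scale: large enough that every
rule is exercised with meaningful margins, small enough that the complete
double-comparative run finishes in well under a minute.

## Known limitations

* Coverage-based segmentation cannot separate same-strand overlapping
  transcripts; internal units inherit their host's 3' end.
* The significance model is a substitute for the original empirical-Bayes
  count analysis: the decision rule is identical, the posterior values are
  not expected to match that tool's numbers.
* The built-in local aligner uses ungapped Karlin–Altschul statistics for
  gapped alignments (as classical ungapped-theory approximations do); for
  the conservation thresholds in use (E ≤ 10⁻⁵ at ≥ 50% coverage) the
  regime is far from the decision boundary.
* Conservation of free-standing transcripts is judged on the best single
  hit; multi-fragment (summed-HSP) coverage is not implemented.
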