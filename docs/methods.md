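# Methods

This note documents the models and procedures srnapipe implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Read preprocessing

Raw reads pass a fixed cascade: 3′-adapter trimming → length window →
junk filter → contaminant annotation → collapsing.

*Adapter trimming* keeps the insert before the leftmost full adapter
occurrence, or before a read-terminal partial match of at least
`adapter_min_overlap` (default 8) adapter-prefix bases; reads with no
qualifying match are discarded. *Length window*: inserts shorter than
`min_len` (19 nt) or longer than `max_len` (24 nt) are removed — the
mature-miRNA size range in plants. *Junk* is operationalized as an insert
containing an ambiguous base (N) or a single-nucleotide homopolymer
covering ≥ `homopolymer_frac` (default 0.80) of its length; upstream
small-RNA vendors use the term without defining it, so this is an explicit
stand-in, and because N-containing inserts are junk by definition no
ambiguous base survives preprocessing.

*Contaminant annotation* is exact-substring membership against per-class
reference sets, with one label per tag assigned by fixed precedence
(rRNA > tRNA > snoRNA > snRNA > other ncRNA > mRNA > repeat > valid).
Published accounting tables let these categories overlap — their rows do
not sum to raw − valid — so a partition had to be imposed to make read
conservation (`raw = removed + junk + Σclasses + valid`) a testable
invariant. Exact matching (no mismatch tolerance) keeps annotation
deterministic and oracle-checkable; the class index is a k-mer set over the
retained length range. Whether the original workflows filter mRNA before or
after the Rfam classes is not documented anywhere we know of; the
precedence here is a design choice, not an inference.

The summary generator recomputes every percentage from counts. One quirk
is supported deliberately: in the bundled published table the five Rfam
subclass rows express their *unique*-read percentage against the *total*
raw-read denominator; `summary_table(..., subclass_unique_vs_total=True)`
reproduces that convention, the default uses the unique denominator
consistently.

## Hairpin model

Folding uses a Nussinov-style dynamic program minimizing a weighted pair
score: G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol, hairpin loops ≥ 3 nt, no
pseudoknots. This is a deliberate simplification of thermodynamic folding
— no stacking, loop entropies or dangles — chosen because every decision
the pipeline takes from a fold (stem-loop topology, arm assignment, MFEI)
only needs a reasonable, *deterministic* structure, and because the DP can
be verified exhaustively against brute-force structure enumeration (the
test suite does this for all sequences up to length 6 and seeded samples up
to length 12). Tie-breaks prefer pairing the 5′-most base with its smallest
admissible partner, so outputs are reproducible to the byte. For users who
want thermodynamic structures, `fold_external` accepts precomputed
(structure, MFE) pairs from any folder and the rest of the pipeline is
agnostic to the backend. Note one consequence of scoring G:U: folding a
sequence and its reverse complement need not give the same |MFE|, because a
G:U pair complements to the unpairable A:C.

MFEI = (|MFE|/length × 100)/GC%. |MFE| is used so the conventional novel
gate reads naturally as MFEI ≥ `mfei_min` (default 0.80); a GC-free
sequence (undefined MFEI) reports 0.0 and therefore fails the gate rather
than erroring.

A precursor is a *valid host* for a mature span when (a) its structure has
exactly one terminal loop, (b) the span lies wholly within one arm, and
(c) at least `mature_paired_min` (default 16) of the mature bases are
paired; novel candidates additionally require the MFEI gate. Published
discovery programs do not publish their exact stem-loop criteria, so
(a)–(c) are this package's operational definition, each reported by name on
failure.

## Discovery rules

Catalog mapping is Hamming distance over equal-length windows with budget
`max_mismatch` (default 1) and *no indels*: the conventional rule is stated
as a mismatch count, and an indel-tolerant mapper would silently change
calls. Conserved classification takes precedence over novel when a tag
satisfies both. Expression is attributed to the mature *sequence*:
identical sequences share counts, and every catalog name carrying that
sequence reports the same abundance. Families are the `miR<number>` token
extracted case-insensitively from the matched name; names without the
token (including all novel candidates) stay unassigned.

## Differential expression

TPM normalizes by the library's *valid-read* total (the natural choice
when the tested population is the valid tags; raw or mapped totals would
change all TPMs by a constant factor). The 2×2 table per miRNA is
[count, total − count] × [treatment, control] — the standard
count-vs-rest contrast. The chi-square statistic is the closed-form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) without continuity correction, p from the
1-df chi-square tail; the Fisher test is two-sided by the
minimum-likelihood rule. Both must reach `alpha` (0.05) and the fold gate
|log₂| ≥ `log2_min` (1.0) for an up/down verdict.

No multiple-testing correction is applied by default, which is faithful to
the convention for single pooled libraries but statistically
non-conservative; `bh_correct=True` applies Benjamini–Hochberg to both
p-value vectors first. Zero-on-one-side miRNAs are flagged
`library_specific` and their ratio is computed with the zero side replaced
by the TPM of one pseudo raw read (`pseudo_count`), since a zero
denominator has no defined fold change. With large counts the chi-square
test is significant for biologically negligible shifts — the worked
example shows a miRNA at p ≈ 3e−6 with |log₂| = 0.28 called `ns` — which
is exactly what the fold-change gate is for.

## Degradome validation

Tags map by exact substring; a multi-mapping tag contributes its full
count at every locus (fractional weighting is a plausible alternative; full
counting is simpler and the choice is isolated in `map_degradome_tags`).
Duplexes are ungapped: the penalty scheme defines mismatch (1) and G:U
(0.5) costs, doubled at miRNA positions 2–13, and defines no gap cost, so
an ungapped scan is the deterministic reading. The predicted cleavage site
is the transcript base paired to miRNA position `cleavage_pos` (10) —
slicing occurs between the bases opposite positions 10 and 11 — and a site
is validated only when a degradome 5′ end coincides with it exactly.
`score_cap` (default 4.0) bounds the accepted duplex penalty; common
target-finder practice, exposed rather than silent.

Categories are evaluated in the order 4 → 0 → 1 → 2 → 3 because the
definitions overlap (a single-read site is also ≤ median); the single-read
rule is unconditional so it goes first. The t-plot median is computed over
*covered* positions only — including zero-count positions would drive the
median to 0 on long transcripts and make category 3 nearly unreachable.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ S) with population TB, successes B,
draws TS — the standard enrichment direction. Genes with no annotation
still count toward TB; the background defaults to every gene in the
annotation table. Significance at p ≤ 0.05, no correction by default, BH
behind a flag.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on
three planes.

*References.* Precursors are built constructively — a 23–29 nt 5′ arm
containing the mature, a 5–8 nt A/C loop, and the reverse-complement arm
with ≤ 2 symmetric mismatches — then verified against the package's own
hairpin validator (single stem-loop, mature within the arm, MFEI ≥ 0.80);
failing draws are resampled. About 30% of precursors also shed an
opposite-arm (star) product, giving planted novel candidates. Half the
transcripts carry a perfect complementary site for a planted miRNA, which
defines the planted cleavage coordinate. One annotation term is
concentrated on target transcripts (80% vs 5% carriage) to give the
enrichment stage known structure.

*Small-RNA libraries.* Per-sRNA base abundance is log-normal
(μ = 5.5, σ = 1 on the log scale — heavy-tailed, like real libraries) and
*shared across libraries*; treatment libraries scale the de_fraction
(30%) of planted miRNAs by 2^±`de_log2fc` with alternating signs, and reads
are drawn multinomially at `library_depth`. The log-normal draw is read as
between-miRNA abundance heterogeneity, not per-library noise: independent
per-library noise would be replicate-free overdispersion that the
chi-square/Fisher machinery deliberately does not model. Contaminant reads
are random fragments of the class references (≈19% of reads across seven
classes), junk reads are homopolymers or N-containing inserts (1%), 2% of
sRNA reads lack the adapter, and all other reads carry the full 3′ adapter.

*Degradome libraries.* Each planted cleavage yields 20–21 nt tags starting
exactly at the planted site with count signal:noise × background
(defaults 10 × 2 = 20); background tags of count 2 start uniformly along
every transcript. Setting the background count to 0 gives the no-noise
limit in which every planted site is its transcript's unique maximum.

What the generator does **not** emulate: sequencing errors and quality
scores, expression-independent biases (ligation, GC), genome-scale
reference complexity, isomiR end-variation, and biological replicates.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic under its own assumptions — not its robustness to
error-containing real reads.

All three generators are deterministic under a fixed seed; per-library and
per-purpose streams are derived from (seed, CRC32(label)) so adding a
library never perturbs another's reads.

## Problem sizes and acceptance metrics

The recovery runs use 30 precursors, 60 transcripts and a library depth of
5×10⁵ reads for differential expression (planted |log₂FC| = 2), the
default degradome settings at signal:noise 10, and noise-free settings for
discovery recall — each reported as the median over three seeds. At this
depth planted miRNAs carry thousands of reads, so the dual test has
essentially full power at 4-fold changes and the fold gate keeps null
miRNAs out: sensitivity ≥ 0.9 and false-discovery proportion ≤ 0.1 hold
with a wide margin. Desk-scale variants of the same runs (10 precursors,
2×10⁴ reads) are used in the unit suite.

## Known limitations

- The Nussinov energy model is not thermodynamic; MFEI values are only
  comparable within this model (planted precursors clear 0.80 easily, as
  real pre-miRNAs do under RNAfold, but the scales differ).
- No isomiR handling: tags map to catalog windows, but counts are not
  aggregated across end-variants.
- Single-label contaminant precedence differs from overlap-tolerant
  annotation used by some vendors; per-class totals are comparable only
  under the same convention.
- Exact-substring degradome mapping cannot place tags across splice or
  sequencing variants; short tags (< 15 nt) are skipped entirely.
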