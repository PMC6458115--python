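# Methods

This note records the models, algorithms, parameter choices and numerical
conventions behind the `satellitome` package, and what its synthetic-data
tests do and do not demonstrate about real libraries.

## Study design being modelled

A female (ZW) and a male (ZZ) individual are shotgun-sequenced at low
coverage (2x250 bp paired-end). Satellite DNA families are discovered from
the unassembled reads, organised into a catalog, and quantified separately
in the two libraries after equalising library size. Because the W
chromosome is female-limited, a family's female/male abundance quotient
(F/M ratio) ranks W-linkage candidates: autosomal families sit near 1,
W-enriched families well above it, and W-exclusive families are absent
from the male library altogether. Monomer-level haplotype networks then
resolve, within one family, which sequence variants are shared between the
sexes (autosomal loci) and which are female-only (W loci). Finally, a
W-specific satellite supports two cheap sex diagnostics: an interphase
quick-FISH spot count and a qPCR ΔCt assay.

## Synthetic data generator

`simdata` plants each family as head-to-tail tandem arrays at uniformly
random, non-overlapping positions (arrays are spliced in, never
overwritten) in i.i.d. random background, one composite sequence per sex.
Chromosomes are not modelled: linkage is a label, and W-linked families
simply receive zero male copies — the downstream mathematics only consumes
per-library nucleotide fractions. Each monomer copy is independently
mutated at the family's per-copy substitution rate with a 2:1
transition:transversion ratio, so the planted divergence is recoverable by
the K2P estimator; indels default to zero to keep truth bookkeeping exact.
The truth table is recomputed from the emitted strings (post-mutation
lengths), coordinates are 0-based half-open, and a fixed seed determines
the output byte-for-byte.

Reads are sampled uniformly (insert length normal, default 450 ± 40 nt,
clipped), the second mate reverse-complemented, substitution errors applied
i.i.d. (default 0.001/base), qualities constant Q30; quality trimming is
exercised by injecting configurable low-quality tails rather than an error
recalibration model. Not modelled: GC bias, PCR duplicates, chimeras,
realistic error profiles — so passing tests certify the algorithms under
clean sampling assumptions, not robustness to platform artifacts.

Canned scenarios (`scenarios.py`) fix the study conditions once: the
abundance-recovery design (five families at 3/1.2/0.6/0.3/0.1% of genome
nucleotides, one W-linked, 20,000 read pairs/sex), the discovery design
(five mutually <70%-identical families at 2/1/0.5/0.2/0.07%, two W-linked,
3 Mb background per sex so that one clustering round samples well below 1x
coverage — the regime real satellite mining operates in, where single-copy
reads rarely overlap and only repeats cluster), and a small end-to-end
configuration for fast pipeline tests. Seeds move only the random monomer
sequences and placements, never the design.

## Discovery loop

Round one samples `round0_n` reads per library (default 4,000) and joins
the sexes; round two doubles the sample; later rounds keep it constant.
Reads are clustered by shared canonical k-mers (k = 13; edge when two reads
share ≥ 20% of the smaller read's distinct k-mers; connected components of
size ≥ 5). The cluster consensus is laid out against an anchor member and
majority-voted per column. The anchor is the most repeat-dense member —
the one with the fewest distinct k-mers, since a tandem read of period p
carries ~p distinct k-mers versus ~read-length for single-copy sequence —
which prevents array/background junction reads from anchoring the layout;
connectivity breaks ties.

Tandem structure is called by self-match periodicity (the dotplot criterion
made quantitative): the smallest lag L whose positional match fraction
reaches 0.7 wins, except that a lag within 10% of it with strictly higher
match fraction is preferred (guarding against noise-shortened periods); the
monomer is the majority base over L-phased columns. Visual cluster-shape
triage is deliberately replaced by this test because it is reproducible.

A called monomer joins the catalog if its circular identity to every
existing entry is below 0.8. Reads matching any catalog monomer at ≥ 0.8
identity over the full read or either half (tandem-tiled, both strands)
are masked from the pool; since survivors already failed the previous
catalog, each round masks only against its new monomers (equivalent and
cheaper). The loop stops when a round adds nothing or at `max_rounds`.
This reproduces the hallmark of iterative mining: abundant families
dominate round one, rare (often W-linked) families surface only after
masking frees the clusters.

## Catalog

Monomers are circular sequences observed at arbitrary phase and strand, so
identity aligns one partner (edlib, free end gaps) against a tandem tiling
of the other and takes the best over strands and directions; the value is
1 − edit distance / query length, which equals matches/columns for
substitution-only divergence and does not depend on aligner tie-breaking.
`canonical_monomer` (lexicographic minimum over all rotations of a monomer
and its reverse complement) provides a stable representative.

One conviction from building this: an optimal global DNA alignment of two
*unrelated* monomers already scores ~55% identity — the twilight floor the
optimiser reaches on chance agreements — so a 40% superfamily threshold on
raw identity alone would connect everything. The homology screens this
cataloguing emulates are *seeded* local searches, for which unrelated pairs
simply produce no hit. Grouping therefore requires a shared exact canonical
11-mer (BLAST-word-like, on the doubled sequences) before a pair's identity
can create an edge; the 95/80/40% thresholds then apply to raw identity
among seeded pairs. Single-linkage components of one weighted graph cut at
the three thresholds give nested partitions by construction. Families are
named `<prefix>SatNNN-RUL` by decreasing female abundance (ties: male
abundance, then lexicographic consensus), NNN zero-padded to three digits.
The thresholds are applied to variant consensus sequences.

## Quantification

Both libraries are downsampled to the same read count (default: the
smaller library) before alignment. Each read is aligned to every catalog
variant it shares a canonical 13-mer with, both strands, against a tandem
tiling of the variant; the glocal edlib alignment is trimmed to its
best-scoring contiguous column run (match +1, mismatch/gap −2 — a local
alignment by Kadane's rule, which clips read tails that run off an array
into background). The single highest-scoring alignment per read wins
(best-hit resolution, preventing double-counting; one hit per read is a
deliberate simplification of per-segment hits — reads spanning two
different families are vanishingly rare at these array sizes). Hits below
identity 0.7 or 20 aligned nucleotides are discarded.

Abundance is Σ aligned_nt / Σ read lengths. The source phrasing
("proportion of the aligned nucleotides within the number of total reads")
is loose; nucleotides are the denominator here, with a read-count mode
behind `denominator="reads"`. Divergence is computed read-vs-consensus (as
masking-based annotation does), per hit K = −½·ln[(1−2P−Q)√(1−2Q)] with
P = transitions/aligned_nt and Q = transversions/aligned_nt; the family
value is the aligned-nt-weighted mean in percent, missing (printed "—")
for a family absent from a library. Hits outside the K2P log domain are
saturated: excluded from the mean, accumulated into the top landscape bin
so that landscape bins always sum exactly to the abundance computed from
the same hits. Landscape bin width defaults to 1%; the subtractive
landscape is the per-bin female − male difference. `fm_ratio` returns
`math.inf` as the absent-in-male flag (naturally sorting above all finite
ratios, as published candidate tables print those rows first) and `None`
when a family is absent from both libraries.

## Monomer haplotype networks

A read is aligned to the tandem-tiled family consensus; every copy whose
full consensus span (positions 0..RUL) lies inside the read is excised,
oriented to the consensus strand and phased to consensus position 0, so
rotations can never create artificial haplotypes; partial flanking copies
are dropped, and copies below 0.8 identity to the consensus are rejected.
Exact sequences collapse into haplotypes with per-library counts;
"singleton" means total count 1 across both libraries pooled (networks are
built on pooled monomers with per-sex colouring). Distances are Hamming
over star-aligned sequences — each haplotype projected onto consensus
columns, gaps a fifth state, insertions relative to the consensus dropped —
a stated approximation to a full multiple alignment, adequate for
near-RUL-length monomers. The MST is Kruskal with deterministic
tie-breaking: among equal weights, edges touching higher-total-count
haplotypes first (goeBURST convention), then lexicographic endpoint
sequences. Exports are GraphML and DOT with node size proportional to
abundance and per-sex counts as attributes.

## Sexing calculators and statistics

quick-FISH: cells with 2 or 3 spots are informative; other counts
(dropout, overlapping signals) are excluded from the denominator but
reported; a specimen is called female/male when the 3-spot (resp. 2-spot)
fraction of informative cells reaches the majority (default 0.8 — below
the ~90% expected-signal rate such preparations achieve, so true specimens
classify), given at least 20 informative cells; counts above 6 are
rejected as implausible. ΔCt: replicate channels whose range exceeds 0.5
cycles (common practice; no published value) reject the record;
ΔCt = mean(Ct_target) − mean(Ct_reference), RQ = E^(−ΔCt) with
amplification efficiency E = 2 by default; SEM propagates as the root sum
of squares. The qPCR sex call uses a given RQ threshold or the geometric
midpoint of known-sex calibration groups; a value exactly at threshold is
ambiguous.

Mann-Whitney U uses midranks for ties and U = min(U_a, U_b). For pooled
n ≤ 12 the two-sided p is exact: all C(n, n_a) assignments of the pooled
values are enumerated and p = P(min-U ≤ observed), which reproduces the
textbook 2-group example p = 1/3 for {1,2} vs {3,4}; larger samples use
the normal approximation with tie correction and continuity correction.
Shapiro-Wilk delegates to scipy's vetted routine behind the package's
input contract; Kruskal-Wallis likewise, with the all-identical case
defined as H = 0, p = 1. All tests are two-sided.

## Pipeline

One config object carries every stage parameter; stage seeds derive from
the master seed by a fixed counter (master × 1009 + stage index, mod 2³¹),
so stages rerun independently and reproduce identical downstream outputs —
the manifest records config, seeds and SHA-256 checksums of every
artifact. Truth-aware scoring matches catalog families to planted families
by best circular identity (≥ 0.7) and calls a family W when its F/M ratio
is absent-in-male or exceeds 5; W recall/precision are scored over matched
families (does the ratio classify linkage correctly), while `family_recall`
reports separately what fraction of planted families discovery captured.

## Test and check sizes

The recovery checks run at the stated study conditions with these problem
sizes, chosen as the package's own test design: abundance recovery
averages estimates over replicate simulated libraries (8 in the test
suite, 6 in the acceptance script) of 20,000 pairs/sex, because the
smallest family (0.1% of nucleotides) occupies only ~40 read pairs per
library and a single draw carries ~15-18% fragment-sampling noise —
averaging isolates method bias (measured ≤ ~10%) from that Poisson noise;
per-read validation against recorded fragment origins shows the aligner
reproduces the realized satellite content of a library to within ~2%.
Discovery convergence runs 20 seeds (8 in the acceptance script) of the
discovery scenario; MST optimality is checked against exhaustive Prüfer
enumeration up to 7 nodes; Mann-Whitney exactness against brute-force
assignment enumeration up to pooled n = 12.

## Known limitations

Single best-hit per read slightly undercounts reads spanning two families;
consensus quality for very long monomers (RUL approaching read length) is
limited because fewer complete copies fit a read, and families with RUL ≥
read length cannot be monomer-harvested at all (the paper-scale analogue
applies to 250 bp reads). The star alignment underestimates steps between
haplotypes carrying insertions at the same position. The discovery loop's
recovery of families below ~0.1% of nucleotides is stochastic at desk
scale, mirroring — intentionally — the behaviour that made iterative
masking necessary in the first place. The bundled published table is an
excerpt (the rounding-stable worked-example rows are exact); recomputing
the full published dataset would require the original sequencing
libraries.
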