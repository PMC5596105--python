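# Methods

This note documents the models, parameter choices and numerical conventions
behind `sporomir`, and what the synthetic-data generator does and does not
emulate.

## Preprocessing

Reads are collapsed to unique tags with one integer count per library; `U`
is normalised to `T` and reads containing other characters are discarded
and counted. The length window is 19–27 nt with both bounds inclusive
(configurable; a wider 19–29 nt window can be selected). Singleton removal
uses the total pooled over all libraries — a sequence seen exactly once
anywhere is removed — because discovery operates on the pooled tag set; a
per-library mode is available. The stage satisfies an exact conservation
identity (reads in = N-containing + length-removed + singletons +
surviving) that the tests assert.

Length-profile modes are local maxima of the pooled histogram, reported
largest-first; on default simulations the top three are the 24-nt, 21/22-nt
and 31-nt classes.

## Conserved matching and isomiRs

Matching is an ungapped sliding alignment of tag against reference: end
offsets up to ±4 nt, overlap ≥17 nt, ≤2 substitutions in the overlap. The
best hit minimises (substitutions, |5′ offset| + |3′ offset|, reference
id); the deterministic tie-break order makes the bulk (vectorised) matcher
and the per-tag matcher provably identical, which the tests check against
a brute-force placement scan.

Offset signs: positive means the tag extends past the reference at that
end, negative means it is trimmed. Extensions are split into templated
(continuing the reference's recorded genomic flank) versus nontemplated 3′
tails (U-run → `tail3_U`, A-run → `tail3_A`, otherwise `tail3_other`);
without flank context an extension is reported with a "template-unknown"
detail rather than an error. A nontemplated 5′ extension has no class of
its own (the class set is closed); it is recorded in the detail string
only — the generator never produces one.

## Novel discovery

**Mapping.** Tags map ungapped to gene-model sequences on both strands with
≤2 mismatches, found by a pigeonhole 6-mer seed search (exhaustive for tags
≥18 nt) and verified by Hamming distance. Multi-mapping tags contribute
1/k of their reads to each of their k placements for locus calling, but
full counts for expression (annotation is per sequence, not per locus).

**Locus calling.** Overlapping placements on one strand merge into stacks;
a stack with weighted total ≥100 reads is a candidate locus. The "at least
100 reads of distinct tags" rule is read as ≥100 reads summed over distinct
tags (not ≥100 distinct tags); the threshold is a parameter.

**Folding.** Windows grow around the modal tag from 80 nt flanks in 20-nt
steps to 300 nt, then — the extended search — in 100-nt steps to 1 kb,
truncating at the gene-model bounds and stopping once the window saturates
or a hairpin validates. The folder is a maximum-weight nested-pairing
(Nussinov-style) dynamic program with pair weights GC=3, AU=2, GU=1 and
minimum hairpin loop 3 nt; traceback is deterministic (the closing base is
paired whenever pairing attains the optimum, with the smallest partner).
This combinatorial model was chosen over a thermodynamic one because it is
dependency-free and exactly verifiable against exhaustive enumeration; a
thermodynamic folder could be substituted behind the same `fold` contract.

**Duplex validation.** The modal tag must lie on one stem arm: no guide
base may pair within the guide (else it spans the terminal loop), and its
partners are reduced to a coherent stem — the longest run of pairs whose
partners descend with guide position (bulge jumps ≤ step+3), merging
consecutive runs while partners keep descending within a duplex-sized span
(guide length + 6). Pass requires ≥14 stem-paired guide positions, ≤5
unpaired and ≤3 bulged. These numeric limits instantiate the community
criteria for plant miRNA annotation, which the underlying study cites
without numbers. A maximum-pairing folder happily pairs random flanks, so
the stem-run reduction is what keeps the duplex geometry honest; the
limits are deliberately not relaxed to compensate.

**Guide and star.** The guide is the most abundant tag on the hairpin; the
ideal star spans the guide's stem partners with a 2-nt 3′ overhang, and the
star is the most abundant opposite-arm tag within 6 nt of that interval
(positional shift = the larger of the two end displacements — a rigid 6-nt
displacement is accepted, 7 nt is not). Because the two arms usually form
separate read stacks, the star search uses all placements on the locus and
strand, not only the triggering stack; if the opposite-arm tag out-counts
the current guide the roles swap, so "higher frequency" always defines the
guide. With no observed star tag the theoretical star sequence is emitted
with count 0. Candidates whose guide matches the reference set are routed
to the conserved side; remaining guides are named `Pab-miRn{serial}_{arm}`
by descending abundance, identical guides from several loci collapsing into
one miRNA with a precursor list.

## Expression and differential expression

The catalog quantified per library is: every tag hitting the reference set
(canonical matures and their isomiRs as separate members), novel guides,
and observed stars — each member is one distinct sequence, so its counts
are the tag's own row. RPKM uses the post-filter library totals and the
mature length in kb. The expression filter keeps members whose mean raw
count within at least one temperature condition is ≥10.

DE between two temperatures uses the classic Z-test on pooled proportions
(Kal's test) on counts pooled within condition; a Fisher exact alternative
and an off-by-default Benjamini–Hochberg correction exist. log₂ ratios are
computed on mean RPKM with a pseudo-value of half the smallest nonzero
RPKM in the matrix (zeros occur; the study is silent on the guard). A
member is a DEM when |log₂ ratio| > 1 and p < 0.05 — both strict — in at
least one of the three contrasts. Both statistics are rounded to 12
decimals before the strict comparison so exact-threshold cases are
classified deterministically.

Profile clusters are not fitted: each contrast contributes a sign (+/−/0
by significance and direction) and the triple is mapped onto the weak
orderings of the three temperatures — exactly 13 of the 27 triples are
consistent, and dropping the flat one leaves exactly 12 non-flat classes.
Inconsistent triples (possible because significance is thresholded per
contrast) are re-signed from the ranks of the condition means and flagged.

Under a null simulation (equal expected proportions, 6+6 libraries,
Poisson counts with lognormal abundance spread) the joint threshold is
strongly conservative: the empirical DEM rate is far below the nominal 5%
because the 2-fold requirement dominates at realistic depths.

## Target prediction and integration

The scanner scores every transcript window against the miRNA antiparallel
(position 1 = miRNA 5′ end): match 0, G:U 0.5, mismatch 1, gap 2, all
doubled at seed positions 2–13; ≤1 gap (the site may be one base shorter
or longer than the miRNA); penalties are handled as ×2 integers so E is an
exact half-integer. A site is reported at E ≤ 3.0 and only the minimum-E
site per (miRNA, transcript) pair is kept (ties: leftmost, then the
ungapped site). Sites with any non-match at miRNA positions 9–11 are
labelled translational, others cleavage — informational only. One unified
scorer replaces the two external servers the original workflow combined.

DEGs are transcripts with |log₂ fold change| > 1 between condition means
in ≥1 contrast (the mRNA table carries means only, mirroring transcript
amounts taken from a companion expression study). Pairs are retained when
the Pearson correlation of the miRNA's and transcript's three condition
means is strictly below −0.6, the miRNA is a DEM and the transcript a DEG;
degenerate (zero-variance) profiles yield undefined r and are flagged, not
retained. Pearson (not Spearman) is the default because three points make
rank correlation nearly degenerate. Retained pairs hitting annotated
epigenetic regulators are tabulated over the closed 8-category schema; the
per-category miRNA/target columns count within the DEM×DEG scan universe,
since that is the universe the pipeline scans.

## The synthetic-data generator

The generator emulates the study design: 18 libraries (A2C/B10W × stages
1–3 × 18/23/28 °C), 100,000 reads each, a 200 kb genome with 300
non-overlapping gene models, 40 planted MIR loci, 60 epigenetic-regulator
transcripts. Reads follow a length mixture — 21/22-nt components are
miRNA-derived, 24-nt (weight 0.33), 31-nt (0.17) and uniform 15–35 nt
(0.15) components are genomic background fragments — so the pooled length
profile is tri-modal and background stacks genuinely exercise the
≥100-read locus threshold (they are rejected later at hairpin validation).

Planted hairpins are mature (21–22 nt) + loop (8–20 nt) + near-reverse
complement with 0–3 designed mismatches; mismatch bases are chosen unable
to pair the guide at all (no Watson–Crick, no wobble), and designs are
rejection-sampled until the hairpin, folded *with its genomic flanks* by
the pipeline's own folder, passes duplex validation — planted loci are
guaranteed true positives at the first 80-nt window. The star strand is
sampled at 1/5–1/20 of the guide (uniform per locus) so the
frequency-based guide rule is decidable. IsomiR modifications
(substitution 2%, 5′ trim 3%, 3′ trim 5%, templated extension 3%,
3′ U-tail 4%, 3′ A-tail 2%) and per-base sequencing errors (0.2%) are
applied per read.

60% of loci get temperature-dependent expression cycling through the 12
profile classes with a 4-fold extreme contrast (1×/4× for two-level
profiles, 1×/2×/4× for three-level). Per-library read shares are
normalised by a fixed temperature-averaged denominator, so planted fold
changes are not attenuated by compositional coupling between loci. Each
temperature-responsive miRNA receives two planted target sites (reverse
complement with 0–2 non-seed mismatches, i.e. E ≤ 2), the first in a
regulator transcript. Linked mRNA profiles are constructed so their
*sample* Pearson correlation with the miRNA profile equals the configured
strength (−0.9) exactly — the residual lives in the unique direction
orthogonal to the profile in the centred 3-point space — with strength −1
giving an exact negative affine image.

What the generator does **not** emulate: platform-specific error profiles
and adapters (reads are emitted pre-trimmed with flat Q30 qualities), the
biology of the 31–32 nt class beyond its length mode, genotype- or
stage-specific expression (the 6 libraries per temperature act as
replicates), isomiR biology beyond independent per-read modification, and
genome-scale mapping ambiguity (200 kb vs a 20 Gb genome). Passing
planted-truth tests therefore demonstrates the pipeline's internal
correctness and calibration, not its performance on real spruce data.

## Problem sizes and determinism

All stochastic components draw from a single seeded generator; simulator
outputs are byte-identical under a fixed seed. The default test suite runs
the full default-scale experiment once (1.8 M reads; about one to two
minutes on one CPU) plus brute-force oracle checks at small n: folding
versus exhaustive structure enumeration at length ≤14, matching/mapping
versus exhaustive scans at 50×50, alignment scoring versus gap-placement
enumeration at miRNA length ≤12, and the null DE calibration at 500 miRNAs
× 200 replicates.
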