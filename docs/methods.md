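# Methods

This note documents the models and procedures implemented in
`circscreen`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)`; conversion
happens only at file boundaries (GTF is 1-based closed, BED 0-based
half-open). Minus-strand transcripts keep exons in genomic order;
transcript-space operations (spliced sequence, window mapping)
reverse-complement on demand. A back-splice junction is stored as a pair
of boundary coordinates in genomic + orientation: the **donor** is the
half-open end of the downstream exon, the **acceptor** the start of the
upstream exon, with `acceptor < donor` on both strands. This single
convention removes the ambiguity that otherwise creeps into junction
arithmetic, at the cost of the donor/acceptor names describing genomic
geometry rather than transcription order on the minus strand.

## Junction discovery

A chimeric record contributes to a junction only if all filters pass:
same contig, same strand, `donor − acceptor ≤ max_span` (default 100,000
bases), and a canonical splice motif. On the + strand the motif is
`genome[donor:donor+2] + genome[acceptor−2:acceptor]` and must equal
GT-AG; on the − strand the reverse-complement equivalents apply
(genomically `CT` after the donor and `AC` before the acceptor). Any N in
the motif fails the check, and coordinates within 2 bp of a contig edge
report `NNNN` rather than raising — ambiguity is treated as failure, not
as an error.

Supporting reads are counted as **distinct read ids**, so duplicate
records (PCR or alignment duplicates) count once and counts are invariant
under record shuffling and duplication. The alternative — counting
records — would let multimapping reads count twice. Output order is
descending count, then contig, then acceptor, making results
deterministic. Junction annotation requires the donor to equal an exon
end and the acceptor an exon start of the same transcript; the spliced
circle length is the sum of that transcript's exon lengths lying fully
inside `[acceptor, donor)`.

## Panel design

Circular targets need a spliced circle of at least `min_circ_length`
(300 nt) and at most one junction per transcript (highest read count
wins; ties break on coordinates). The amplicon is the last
`amplicon_flank` bases of the circle followed by its first
`amplicon_flank` bases, so the junction sits exactly at offset
`amplicon_flank`. The default flank of 60 nt/side is a typical targeted
amplicon scale; any flank ≥ 25 keeps the downstream counting rule
meaningful. PCR primer thermodynamics are deliberately not modeled —
targets are emitted as amplicon references with junction offsets, which
is all the downstream computation needs.

Linear controls are placed in **spliced transcript coordinates** — the
only space in which "300 nt upstream" is well defined for multi-exon
genes — as a window of `2 × amplicon_flank` nt ending `linear_offset` nt
5′ of the circle, falling back to `linear_offset` nt 3′ of it, and
erroring only when neither fits. A circle whose transcript has no room
keeps a `no_linear` flag instead of failing the whole panel, mirroring
real panels that carry circles without a cognate linear control.

Negative controls are exon-boundary pairs drawn uniformly (seeded,
without replacement) from all transcripts after excluding every observed
junction; they are built exactly like circ amplicons so they measure the
background of the junction-counting rule itself. Candidates are drawn
from all transcripts, not only genes absent from the circ set; a stricter
pool can be arranged by passing a filtered transcript list.

Padlock probes target the cDNA (reverse complement of the amplicon): the
3′ arm is complementary to the `arm_length` cDNA bases ending at the
junction, the 5′ arm to the bases starting at it, so the ligated
arm-to-arm concatenation is exactly complementary to the `2 × arm_length`
window centered on the junction. The per-arm length defaults to 20 nt
(the alternative reading — 20 nt total — would give 10-nt arms, too short
to ligate specifically at padlock assay temperatures). Barcodes are 4 nt;
assignment is a seeded greedy search over all 256 codes enforcing a
pairwise Hamming distance (default ≥ 2, so any single-cycle miscall
cannot convert one valid barcode into another). The greedy search reports
the achievable count when a request is infeasible; it does not compute
the true combinatorial maximum, which is a clique-number problem.

## Quantification

A span `[start, end)` on a circular or negative amplicon with junction
offset `j` qualifies iff `start ≤ j − 25` and `end ≥ j + 25` — at least
50 bases mapped over the middle, 25 on each side of the back-splice.
Linear targets apply the same rule around the midpoint `floor(length/2)`
(the midpoint convention is unstated in the assay description; floor is
symmetric and deterministic). Counts are distinct qualifying read ids per
target and sample.

Normalization divides each count by the **total reads generated for the
sample** — not the column sum — so off-target reads still dilute the
library. Relative circular expression is `circ/(circ + linear)`; 0/0 is
undefined and excluded from summaries rather than imputed. Display-scale
transforms use `log10(x + 1)`, mapping zero counts to zero. Panel versus
RNA-seq concordance is the squared Pearson correlation of the
log-transformed counts over shared targets — symmetric in its inputs and
matching the display scale, since the transform behind published R²
values of this kind is rarely stated. Sample clustering uses
1 − Pearson correlation between sample profiles with average linkage
(scale-robust for expression profiles; both metric and linkage are
arguments), serialized to Newick. The ΔΔCt utility is
`2^−((Ct_t − Ct_ref) − (Ct_cal − Ct_cal_ref))`.

## In situ decoding

Spot detection: white top-hat with a disk of `tophat_radius` (5 px),
global threshold at `spot_min_intensity`, watershed seeded from local
maxima to split touching blobs, one intensity-weighted centroid per
region. The intensity floor defaults to 50 (arbitrary units): rolling
circle products are bright (hundreds of units at typical exposure) while
camera background sits well below, and a floor above the background tail
keeps the detector from flooding the base caller with noise spots.

Base calling: the base is the argmax channel (ties resolved in fixed
A>C>G>T order), quality is `max/Σ` over the four channels. For four
channels this statistic ranges exactly from 0.25 (all equal) to 1.0 (one
hot), which is the printed range of the quality score this field uses;
among the obvious candidates (max/Σ, max/second, margin) only max/Σ has
these bounds. An all-zero vector calls `N` at quality 0.25 and is
flagged. Transcript quality is the **minimum** per-base quality, so one
bad cycle disqualifies the whole barcode. The quality threshold defaults
to 0.45, the midpoint of the 0.40–0.55 band in which such screens
typically operate.

Barcode matching is exact — no 1-mismatch rescue — because codebooks
built at Hamming distance ≥ 2 make rescue unnecessary at 4 cycles and
rescue would silently convert miscalls into counts. Nuclei are segmented
from DAPI by Gaussian smoothing (σ = 2), Otsu threshold, hole filling and
a distance-transform watershed; a blank image returns an empty mask.
Compartment assignment is centroid membership in the mask: nuclear iff
the label at the rounded spot pixel is positive. With widefield imaging
some true cytoplasmic signal overlying a nucleus is called nuclear; no
3-D correction is attempted. The per-target nuclear ratio is
`nuclear/total` over assigned signals, undefined (excluded) for targets
with none. Cross-cycle registration is assumed done upstream; a
rigid-translation aligner (`register_translation`) is provided for
synthetic data only.

## Synthetic data

Generators are pure functions of their `SimConfig` (seed included); reruns
are byte-identical, and sub-streams are derived deterministically per
generator so adding one stage never perturbs another.

The toy genome stamps canonical splice motifs (GT…AG in transcript
orientation) into every intron and around terminal exons, so every
exon-boundary pair is a motif-valid back-splice candidate and the motif
filter is exercised by decoys rather than by accident. Defaults — 20
genes, 3–6 exons of 150–300 nt, introns of 80–400 nt, half the genes
carrying one back-splice — give 10 planted junctions whose circles are
all ≥ 300 nt; planted junction pairs prefer exon pairs that leave spliced
room for a linear control, since real circles rarely consume their whole
host transcript. Chimeric libraries distribute 1,000 reads multinomially
over junctions; panel libraries distribute `depth` reads over targets
with a configurable probability (`cover_prob`, default 0.8) that a read
satisfies the 25-per-side rule — the assay description gives no such
fraction, and 0.8 keeps both branches of the counting rule exercised
without dominating either. RNase-R mode zeroes linear abundances before
sampling, reproducing the loss of linear signal with preserved circular
signal.

Image stacks render nuclei as disks (radius 20–30 px in a 512-px field,
sized so ~500 spots at 8-px minimum separation fit inside and outside
nuclei), spots as Gaussian blobs (σ = 1.2, amplitude 200 with 10%
jitter under noise) in the channel of the barcode base for each cycle,
plus truncated-Gaussian background of scale `channel_noise` (default 5).
The generator does **not** emulate optical point-spread functions,
channel crosstalk, cycle phasing, tissue autofluorescence or sequencing
errors in reads — so passing tests demonstrate the correctness of the
decoding and counting logic under the stated noise model, not robustness
to every artifact of real tissue data.

## Problem sizes and determinism

The test suite and the acceptance checks run on the generator defaults
above (20 genes, 10³–10⁴ reads, one 512-px field with ~500 spots), sizes
at which every pipeline property under test — exact planted recovery,
boundary behavior of the counting rule, binomial-error parameter
recovery — is already fully expressed. All randomness flows from
explicit seeds; hypothesis-based property tests run derandomized.

## Known limitations

- Discovery consumes chimeric-segment records; it does not align reads,
  and fragment-geometry (paired-end) evidence and intronic/lariat
  circles are out of scope.
- Primer thermodynamics, cross-hybridization and probe secondary
  structure are not modeled in panel design.
- Differential expression and batch correction are out of scope for
  quantification.
- The in situ module assumes pre-registered cycles and performs no
  crosstalk or phasing correction; compartment calls are 2-D
  centroid-based.
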