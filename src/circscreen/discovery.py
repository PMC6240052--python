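"""Back-splice junction calling from chimeric read records.

A back-splice joins a downstream (3') splice donor to an upstream (5')
splice acceptor on the same chromosome and strand, with the acceptor at
most ``max_span`` bases upstream in genomic + orientation.  Only junctions
with canonical GT-AG splice dinucleotides are kept by default, and the
boundaries must coincide with annotated exon boundaries.

Coordinates: the donor is the 0-based half-open genomic *end* of the
downstream exon; the acceptor is the 0-based genomic *start* of the
upstream exon.  ``acceptor < donor`` always holds, for both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_formats import (
    ChimericRecord,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)


@dataclass(frozen=True)
class DiscoveryParams:
    """Filters applied to chimeric records before a junction is emitted.

    ``max_span`` is the maximum genomic distance (bases) between acceptor
    and donor; ``required_motif`` is the donor/acceptor dinucleotide pair
    (``None`` disables the motif check).
    """

    max_span: int = 100_000
    required_motif: str | None = "GTAG"
    require_same_contig: bool = True
    require_same_strand: bool = True
    require_exon_boundaries: bool = True

    def __post_init__(self) -> None:
        if self.max_span <= 0:
            raise ValueError("max_span must be > 0")
        if self.required_motif is not None:
            if set(self.required_motif) - set("ACGT") or len(self.required_motif) != 4:
                raise ValueError("required_motif must be 4 letters from A/C/G/T")


@dataclass(frozen=True)
class BackspliceJunction:
    """One back-splice junction with supporting-read count and motif."""

    contig: str
    strand: str
    donor: int      # 0-based half-open end of the downstream exon
    acceptor: int   # 0-based start of the upstream exon
    count: int = 1
    motif: str = ""
    transcript_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.acceptor >= self.donor:
            raise ValueError(
                f"acceptor ({self.acceptor}) must lie upstream of donor "
                f"({self.donor}) in genomic + orientation"
            )
        if self.count < 1:
            raise ValueError("supporting read count must be >= 1")

    @property
    def junction_id(self) -> str:
        return f"{self.contig}:{self.acceptor}-{self.donor}:{self.strand}"

    def span(self) -> int:
        return self.donor - self.acceptor


def check_splice_motif(
    junction: BackspliceJunction, genome: GenomeSequence
) -> tuple[bool, str]:
    """Check the GT-AG splice dinucleotides at a junction.

    On the + strand the donor GT sits immediately after the donor boundary
    and the acceptor AG immediately before the acceptor boundary; on the -
    strand the reverse-complement equivalents apply.  Any N fails.  Within
    2 bp of a contig edge the motif is reported as ``"NNNN"`` and fails.
    """
    seq = genome[junction.contig]
    d, a = junction.donor, junction.acceptor
    if a < 2 or d + 2 > len(seq):
        return False, "NNNN"
    after_donor = seq[d : d + 2]
    before_acceptor = seq[a - 2 : a]
    if junction.strand == "+":
        motif = after_donor + before_acceptor
    else:
        motif = reverse_complement(before_acceptor) + reverse_complement(after_donor)
    return (motif == "GTAG" and "N" not in motif), motif


def call_backsplice_junctions(
    records: Iterable[ChimericRecord],
    genome: GenomeSequence,
    params: DiscoveryParams = DiscoveryParams(),
) -> list[BackspliceJunction]:
    """Call back-splice junctions from chimeric records.

    Records failing any filter (cross-contig, cross-strand, span over
    ``max_span``, non-canonical motif) are discarded.  One junction is
    emitted per unique (contig, strand, donor, acceptor) with count equal
    to the number of distinct supporting read ids.  Output is sorted by
    descending count, then contig, then acceptor.
    """
    supporters: dict[tuple[str, str, int, int], set[str]] = {}
    motifs: dict[tuple[str, str, int, int], str] = {}
    for rec in records:
        if rec.contig_a not in genome:
            raise KeyError(f"contig {rec.contig_a!r} absent from genome")
        if rec.contig_b not in genome:
            raise KeyError(f"contig {rec.contig_b!r} absent from genome")
        if params.require_same_contig and rec.contig_a != rec.contig_b:
            continue
        if params.require_same_strand and rec.strand_a != rec.strand_b:
            continue
        acceptor, donor = rec.junc_left, rec.junc_right
        if acceptor >= donor:
            continue
        if donor - acceptor > params.max_span:
            continue
        key = (rec.contig_a, rec.strand_a, donor, acceptor)
        if key not in motifs:
            junction = BackspliceJunction(
                contig=rec.contig_a, strand=rec.strand_a,
                donor=donor, acceptor=acceptor,
            )
            _, motif = check_splice_motif(junction, genome)
            motifs[key] = motif
            if params.required_motif is not None and (
                motif != params.required_motif or "N" in motif
            ):
                motifs[key] = "FAIL:" + motif
        if motifs[key].startswith("FAIL:"):
            continue
        supporters.setdefault(key, set()).add(rec.read_id)

    junctions = [
        BackspliceJunction(
            contig=contig, strand=strand, donor=donor, acceptor=acceptor,
            count=len(reads), motif=motifs[(contig, strand, donor, acceptor)],
        )
        for (contig, strand, donor, acceptor), reads in supporters.items()
    ]
    junctions.sort(key=lambda j: (-j.count, j.contig, j.acceptor, j.donor))
    return junctions


def annotate_exon_boundaries(
    junctions: Iterable[BackspliceJunction],
    transcripts: Sequence[TranscriptModel],
    require_exon_boundaries: bool = True,
) -> list[BackspliceJunction]:
    """Match junctions to transcripts whose exon boundaries they hit exactly.

    A junction matches a transcript iff its donor equals some exon end and
    its acceptor equals some exon start of that transcript (genomic
    half-open boundaries, same contig and strand).  When
    ``require_exon_boundaries`` is set, unmatched junctions are dropped.
    """
    by_location: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_location.setdefault((t.contig, t.strand), []).append(t)
    out = []
    for j in junctions:
        matched = tuple(
            t.transcript_id
            for t in by_location.get((j.contig, j.strand), [])
            if any(e == j.donor for _, e in t.exons)
            and any(s == j.acceptor for s, _ in t.exons)
        )
        if matched:
            out.append(replace(j, transcript_ids=matched))
        elif not require_exon_boundaries:
            out.append(replace(j, transcript_ids=()))
    return out


def spliced_circ_length(
    junction: BackspliceJunction, transcript: TranscriptModel
) -> int:
    """Length of the mature circle: exonic bases within [acceptor, donor).

    Sums the lengths of the transcript's exons lying fully inside the
    junction span (introns spliced out).
    """
    if transcript.transcript_id not in junction.transcript_ids:
        raise ValueError(
            f"junction {junction.junction_id} is not matched to transcript "
            f"{transcript.transcript_id!r}"
        )
    return sum(
        e - s
        for s, e in transcript.exons
        if s >= junction.acceptor and e <= junction.donor
    )
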