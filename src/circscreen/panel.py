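"""Enrichment-panel design: circular targets, linear controls, negative
controls, padlock probes and barcodes.

A circular target's amplicon spans the back-splice junction: it is the
last ``amplicon_flank`` bases of the mature circle joined to its first
``amplicon_flank`` bases, so primers "face outwards" on the genome while
the amplicon reads straight through the junction.  Linear controls sit on
the same transcript, offset from the circle, and measure the cognate
linear isoform.  Negative controls are unobserved exon-boundary pairs
built exactly like circ amplicons to estimate background.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .discovery import BackspliceJunction, spliced_circ_length
from .io_formats import (
    FormatError,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
)


@dataclass(frozen=True)
class DesignParams:
    """Panel design knobs.

    ``min_circ_length`` — minimum mature-circle length (nt) for a circRNA
    to be targetable.  ``linear_offset`` — distance (spliced nt) between
    circle and linear-control window.  ``amplicon_flank`` — bases kept on
    each side of the junction; must be at least the 25-nt counting side
    rule so junction-spanning reads remain callable.
    """

    min_circ_length: int = 300
    linear_offset: int = 300
    n_negative: int = 15
    amplicon_flank: int = 60
    negative_seed: int = 0
    one_per_transcript: bool = True

    def __post_init__(self) -> None:
        for name in ("min_circ_length", "linear_offset", "n_negative", "amplicon_flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.amplicon_flank < 25:
            raise ValueError(
                "amplicon_flank must be >= 25 to satisfy the junction "
                "counting rule"
            )


@dataclass(frozen=True)
class PanelTarget:
    """One amplicon reference in the panel (circ | linear | negative)."""

    target_id: str
    target_class: str
    gene_id: str
    sequence: str
    junction_offset: int | None
    contig: str
    strand: str
    footprint: tuple[tuple[int, int], ...]
    source_junction: str | None = None
    no_linear: bool = False

    def __post_init__(self) -> None:
        if self.target_class not in ("circ", "linear", "negative"):
            raise ValueError(f"unknown target class {self.target_class!r}")
        if self.target_class in ("circ", "negative") and self.junction_offset is None:
            raise ValueError(f"{self.target_class} target needs a junction offset")
        if self.target_class == "linear" and self.junction_offset is not None:
            raise ValueError("linear targets have no junction offset")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PadlockProbe:
    """A padlock probe whose two arms ligate across the back-splice on cDNA."""

    probe_id: str
    target_id: str
    arm_3p: str
    arm_5p: str
    barcode: str
    backbone: str


class Codebook(dict):
    """Barcode (4-nt string) -> target id; unique in both directions."""

    def __setitem__(self, barcode: str, target_id: str) -> None:
        if barcode in self:
            raise ValueError(f"duplicate barcode {barcode!r}")
        super().__setitem__(barcode, target_id)

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self))) if self else 0

    def target_to_barcode(self) -> dict[str, str]:
        return {t: b for b, t in self.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#barcode\ttarget_id\n")
            for barcode, target in self.items():
                fh.write(f"{barcode}\t{target}\n")

    @classmethod
    def from_tsv(cls, path) -> "Codebook":
        book = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                barcode, target = line.rstrip("\n").split("\t")
                book[barcode] = target
        return book


# ---------------------------------------------------------------------------
# target selection


def select_circ_targets(
    junctions: Sequence[BackspliceJunction],
    transcripts: Sequence[TranscriptModel],
    params: DesignParams = DesignParams(),
) -> list[tuple[BackspliceJunction, TranscriptModel]]:
    """Pick targetable junctions, at most one per transcript.

    Keeps junctions whose mature circle is at least ``min_circ_length`` nt
    on a matched transcript; when several junctions share a transcript the
    highest supporting-read count wins.  Returns (junction, transcript)
    pairs ordered by descending count.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    best: dict[str, tuple[BackspliceJunction, TranscriptModel]] = {}
    for j in sorted(junctions, key=lambda j: (-j.count, j.contig, j.acceptor)):
        for tid in j.transcript_ids:
            transcript = by_id[tid]
            if spliced_circ_length(j, transcript) < params.min_circ_length:
                continue
            if params.one_per_transcript:
                if tid not in best:
                    best[tid] = (j, transcript)
            else:
                best[f"{tid}|{j.junction_id}"] = (j, transcript)
    # A junction that won on several transcripts is emitted once, with the
    # first transcript in sorted order.
    seen: set[str] = set()
    selected = []
    for j, t in sorted(best.values(), key=lambda jt: (-jt[0].count, jt[0].contig, jt[0].acceptor)):
        if j.junction_id in seen:
            continue
        seen.add(j.junction_id)
        selected.append((j, t))
    return selected


def circle_sequence(
    junction: BackspliceJunction,
    transcript: TranscriptModel,
    genome: GenomeSequence,
) -> str:
    """Mature circle sequence: exons within [acceptor, donor), strand-oriented."""
    parts = [
        genome.fetch(transcript.contig, s, e)
        for s, e in transcript.exons
        if s >= junction.acceptor and e <= junction.donor
    ]
    seq = "".join(parts)
    if not seq:
        raise FormatError(
            f"junction {junction.junction_id} contains no exon of "
            f"{transcript.transcript_id!r}"
        )
    return reverse_complement(seq) if transcript.strand == "-" else seq


def build_circ_amplicon(
    junction: BackspliceJunction,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    params: DesignParams = DesignParams(),
    target_class: str = "circ",
    target_id: str | None = None,
) -> PanelTarget:
    """Build the junction-spanning amplicon for one circle.

    The amplicon is the last ``amplicon_flank`` nt of the circle followed
    by its first ``amplicon_flank`` nt, so the back-splice junction sits
    exactly at offset ``amplicon_flank``.
    """
    circ_seq = circle_sequence(junction, transcript, genome)
    flank = params.amplicon_flank
    if len(circ_seq) < 2 * flank:
        raise FormatError(
            f"circle {junction.junction_id} is {len(circ_seq)} nt, shorter "
            f"than 2 x flank ({2 * flank}); use a smaller amplicon_flank"
        )
    amplicon = circ_seq[-flank:] + circ_seq[:flank]
    footprint = _junction_footprint(junction, transcript, flank)
    return PanelTarget(
        target_id=target_id or f"{target_class}|{junction.junction_id}",
        target_class=target_class,
        gene_id=transcript.gene_id,
        sequence=amplicon,
        junction_offset=flank,
        contig=junction.contig,
        strand=junction.strand,
        footprint=footprint,
        source_junction=junction.junction_id,
    )


def _junction_footprint(
    junction: BackspliceJunction, transcript: TranscriptModel, flank: int
) -> tuple[tuple[int, int], ...]:
    """Genomic intervals covered by the two amplicon halves."""
    exons = [
        (s, e)
        for s, e in transcript.exons
        if s >= junction.acceptor and e <= junction.donor
    ]
    total = sum(e - s for s, e in exons)
    sub = TranscriptModel(
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        contig=transcript.contig,
        strand=transcript.strand,
        exons=tuple(exons),
    )
    head = sub.transcript_to_genomic_intervals(0, min(flank, total))
    tail = sub.transcript_to_genomic_intervals(max(0, total - flank), total)
    return tuple(sorted(set(head) | set(tail)))


def place_linear_control(
    junction: BackspliceJunction,
    transcript: TranscriptModel,
    genome: GenomeSequence,
    params: DesignParams = DesignParams(),
    target_id: str | None = None,
) -> PanelTarget:
    """Place the linear-isoform control window on the same transcript.

    In spliced transcript coordinates, a window of 2 x ``amplicon_flank``
    nt ends ``linear_offset`` nt upstream (5') of the circle's acceptor if
    the transcript has room; otherwise it starts ``linear_offset`` nt
    downstream (3') of the circle's donor.  Neither fitting is an error.
    """
    window = 2 * params.amplicon_flank
    spliced = transcript.spliced_sequence(genome)
    total = len(spliced)
    # transcript coordinates of the circle span (5'->3')
    c1 = transcript.genomic_to_transcript(junction.acceptor)
    c2 = transcript.genomic_to_transcript(junction.donor)
    circ_start, circ_end = min(c1, c2), max(c1, c2)
    up_end = circ_start - params.linear_offset
    down_start = circ_end + params.linear_offset
    if up_end - window >= 0:
        t_start, t_end = up_end - window, up_end
    elif down_start + window <= total:
        t_start, t_end = down_start, down_start + window
    else:
        raise FormatError(
            f"transcript {transcript.transcript_id!r} ({total} nt spliced) "
            "has no room for a linear control upstream or downstream of "
            f"circle {junction.junction_id}"
        )
    footprint = transcript.transcript_to_genomic_intervals(t_start, t_end)
    return PanelTarget(
        target_id=target_id or f"linear|{transcript.transcript_id}|{t_start}",
        target_class="linear",
        gene_id=transcript.gene_id,
        sequence=spliced[t_start:t_end],
        junction_offset=None,
        contig=transcript.contig,
        strand=transcript.strand,
        footprint=footprint,
        source_junction=junction.junction_id,
    )


def enumerate_negative_candidates(
    transcripts: Sequence[TranscriptModel],
    observed: Iterable[BackspliceJunction],
    params: DesignParams = DesignParams(),
) -> list[tuple[BackspliceJunction, TranscriptModel]]:
    """All unobserved exon-boundary pairs big enough to carry an amplicon."""
    observed_keys = {
        (j.contig, j.strand, j.acceptor, j.donor) for j in observed
    }
    candidates = []
    for t in transcripts:
        for (a_start, _), (_, d_end) in itertools.product(t.exons, t.exons):
            if a_start >= d_end:
                continue
            key = (t.contig, t.strand, a_start, d_end)
            if key in observed_keys:
                continue
            length = sum(
                e - s for s, e in t.exons if s >= a_start and e <= d_end
            )
            if length < 2 * params.amplicon_flank:
                continue
            j = BackspliceJunction(
                contig=t.contig, strand=t.strand, donor=d_end,
                acceptor=a_start, count=1, motif="",
                transcript_ids=(t.transcript_id,),
            )
            candidates.append((j, t))
    return candidates


def sample_negative_controls(
    transcripts: Sequence[TranscriptModel],
    observed: Sequence[BackspliceJunction],
    genome: GenomeSequence,
    params: DesignParams = DesignParams(),
) -> list[PanelTarget]:
    """Sample ``n_negative`` unsupported back-splice sites as background
    controls, built exactly like circ amplicons, seeded and reproducible."""
    candidates = enumerate_negative_candidates(transcripts, observed, params)
    if len(candidates) < params.n_negative:
        raise FormatError(
            f"only {len(candidates)} negative-control candidates available, "
            f"{params.n_negative} requested"
        )
    rng = np.random.default_rng(params.negative_seed)
    idx = rng.choice(len(candidates), size=params.n_negative, replace=False)
    out = []
    for k, i in enumerate(sorted(int(x) for x in idx)):
        junction, transcript = candidates[i]
        out.append(
            build_circ_amplicon(
                junction, transcript, genome, params,
                target_class="negative",
                target_id=f"negative|{junction.junction_id}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# padlock probes and barcodes


def design_padlock_probe(
    target: PanelTarget,
    barcode: str,
    arm_length: int = 20,
    anchor_site: str = "TCGTCGGCAGCGTC",
    probe_id: str | None = None,
) -> PadlockProbe:
    """Design the padlock probe that ligates across a target's junction.

    The probe hybridizes to cDNA (the reverse complement of the amplicon):
    the 3' arm is complementary to the ``arm_length`` cDNA bases ending at
    the junction, the 5' arm to the ``arm_length`` bases starting at it.
    On perfect hybridization the two arms meet and ligate; the backbone
    carries the sequencing anchor-primer site plus the 4-nt barcode.
    """
    if len(barcode) != 4:
        raise ValueError(f"barcode must be 4 nucleotides, got {barcode!r}")
    if target.junction_offset is None:
        raise ValueError(f"target {target.target_id!r} has no junction")
    j = target.junction_offset
    if j < arm_length or len(target.sequence) - j < arm_length:
        raise FormatError(
            f"target {target.target_id!r}: needs {arm_length} nt on each "
            f"side of the junction, has {j} and {len(target.sequence) - j}"
        )
    cdna = reverse_complement(target.sequence)
    jc = len(cdna) - j  # junction position in cDNA coordinates
    arm_3p = reverse_complement(cdna[jc - arm_length : jc])
    arm_5p = reverse_complement(cdna[jc : jc + arm_length])
    return PadlockProbe(
        probe_id=probe_id or f"plp|{target.target_id}",
        target_id=target.target_id,
        arm_3p=arm_3p,
        arm_5p=arm_5p,
        barcode=barcode,
        backbone=anchor_site + barcode,
    )


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b, strict=True))


def assign_barcodes(
    target_ids: Sequence[str],
    barcode_length: int = 4,
    min_pairwise_hamming: int = 2,
    seed: int = 0,
) -> Codebook:
    """Assign each target a unique barcode with a pairwise-distance guarantee.

    Seeded greedy search over all 4^``barcode_length`` codes: shuffle, then
    accept each code whose Hamming distance to every accepted code is at
    least ``min_pairwise_hamming``.  Raises if the request is infeasible,
    reporting the achievable count.
    """
    if len(set(target_ids)) != len(target_ids):
        raise ValueError("target ids must be unique")
    n_codes = 4 ** barcode_length
    if len(target_ids) > n_codes:
        raise ValueError(
            f"{len(target_ids)} targets requested but only {n_codes} codes "
            f"of length {barcode_length} exist"
        )
    codes = [
        "".join(c)
        for c in itertools.product("ACGT", repeat=barcode_length)
    ]
    rng = np.random.default_rng(seed)
    rng.shuffle(codes)
    chosen: list[str] = []
    for code in codes:
        if all(hamming(code, c) >= min_pairwise_hamming for c in chosen):
            chosen.append(code)
        if len(chosen) == len(target_ids):
            break
    if len(chosen) < len(target_ids):
        raise ValueError(
            f"only {len(chosen)} barcodes of length {barcode_length} "
            f"achievable at pairwise Hamming distance "
            f">= {min_pairwise_hamming}; {len(target_ids)} requested"
        )
    book = Codebook()
    for code, tid in zip(chosen, target_ids):
        book[code] = tid
    return book


def write_probes(probes: Iterable[PadlockProbe], path) -> None:
    with open(path, "w") as fh:
        fh.write("#probe_id\ttarget_id\tarm_3p\tarm_5p\tbarcode\tbackbone\n")
        for p in probes:
            fh.write(
                f"{p.probe_id}\t{p.target_id}\t{p.arm_3p}\t{p.arm_5p}\t"
                f"{p.barcode}\t{p.backbone}\n"
            )


def design_panel(
    junctions: Sequence[BackspliceJunction],
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    params: DesignParams = DesignParams(),
    barcode_seed: int = 0,
) -> tuple[list[PanelTarget], list[PadlockProbe], Codebook]:
    """Full panel: circ targets + linear controls + negatives + probes.

    Linear controls are skipped (not fatal) for transcripts with no room,
    mirroring circles that lack a cognate linear control.
    """
    selected = select_circ_targets(junctions, transcripts, params)
    targets: list[PanelTarget] = []
    for junction, transcript in selected:
        circ = build_circ_amplicon(junction, transcript, genome, params)
        targets.append(circ)
        try:
            targets.append(
                place_linear_control(junction, transcript, genome, params)
            )
        except FormatError:
            targets[-1] = PanelTarget(
                **{**circ.__dict__, "no_linear": True}
            )
    targets.extend(
        sample_negative_controls(transcripts, junctions, genome, params)
    )
    junction_targets = [t for t in targets if t.junction_offset is not None]
    book = assign_barcodes(
        [t.target_id for t in junction_targets], seed=barcode_seed
    )
    to_barcode = book.target_to_barcode()
    probes = [
        design_padlock_probe(t, to_barcode[t.target_id])
        for t in junction_targets
    ]
    return targets, probes, book
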