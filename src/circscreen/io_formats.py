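"""Readers and writers for every on-disk artifact the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open ``[start, end)``.  Conversion
happens only at file boundaries: GTF is 1-based closed, BED is 0-based
half-open.  Minus-strand transcripts keep their exons in genomic order;
transcript-coordinate operations reverse-complement on demand.

Chimeric TSV dialect (one record per line, tab-separated)::

    read_id contigA strandA startA endA contigB strandB startB endB junc_left junc_right

``junc_left`` is the acceptor boundary (0-based genomic start of the
upstream exon) and ``junc_right`` the donor boundary (0-based half-open
genomic end of the downstream exon) of the putative back-splice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CHIMERIC_COLUMNS = (
    "read_id contigA strandA startA endA contigB strandB startB endB "
    "junc_left junc_right"
).split()

SPAN_COLUMNS = ["sample_id", "target_id", "read_id", "start", "end"]


class FormatError(ValueError):
    """Raised for malformed input files or invariant violations."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(dict):
    """Mapping of contig name to uppercase nucleotide string (A/C/G/T/N)."""

    def __setitem__(self, name: str, seq: str) -> None:
        if name in self:
            raise FormatError(f"duplicate contig name: {name!r}")
        seq = seq.upper()
        if not seq:
            raise FormatError(f"empty sequence for contig {name!r}")
        bad = set(seq) - _ALPHABET
        if bad:
            raise FormatError(
                f"contig {name!r} contains characters outside A/C/G/T/N: {sorted(bad)}"
            )
        super().__setitem__(name, seq)

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``contig[start:end)``; out-of-bounds is an error."""
        if contig not in self:
            raise KeyError(f"contig {contig!r} not in genome")
        seq = self[contig]
        if not (0 <= start <= end <= len(seq)):
            raise FormatError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered list of genomic exon intervals.

    Exons are ``[start, end)`` in genomic coordinates, sorted by start and
    non-overlapping, all on one contig and strand.  For minus-strand
    transcripts the genomic order is kept; 5'->3' traversal reverses it.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise FormatError(f"transcript {self.transcript_id!r} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise FormatError(
                    f"transcript {self.transcript_id!r}: exon [{start}, {end}) "
                    "has length < 1"
                )
            if prev_end is not None and start < prev_end:
                raise FormatError(
                    f"transcript {self.transcript_id!r}: exons overlap or are "
                    "unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        """Spliced transcript sequence in 5'->3' (strand) orientation."""
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic boundary to a spliced-transcript coordinate.

        ``pos`` must coincide with an exon boundary or lie inside an exon.
        For minus-strand transcripts the returned coordinate counts from the
        transcript 5' end (genomic right).
        """
        offset = 0
        plus_coord = None
        for start, end in self.exons:
            if start <= pos <= end:
                plus_coord = offset + (pos - start)
                break
            offset += end - start
        if plus_coord is None:
            raise FormatError(
                f"position {pos} not inside an exon of {self.transcript_id!r}"
            )
        if self.strand == "+":
            return plus_coord
        return self.spliced_length() - plus_coord

    def transcript_to_genomic_intervals(
        self, t_start: int, t_end: int
    ) -> tuple[tuple[int, int], ...]:
        """Genomic footprint of spliced-transcript window ``[t_start, t_end)``."""
        total = self.spliced_length()
        if not (0 <= t_start < t_end <= total):
            raise FormatError(
                f"transcript window [{t_start}, {t_end}) outside "
                f"[0, {total}) for {self.transcript_id!r}"
            )
        if self.strand == "-":
            t_start, t_end = total - t_end, total - t_start
        out = []
        offset = 0
        for start, end in self.exons:
            length = end - start
            lo = max(t_start, offset)
            hi = min(t_end, offset + length)
            if lo < hi:
                out.append((start + lo - offset, start + hi - offset))
            offset += length
        return tuple(out)


@dataclass(frozen=True)
class ChimericRecord:
    """One chimeric read: two aligned segments plus the junction boundaries."""

    read_id: str
    contig_a: str
    strand_a: str
    start_a: int
    end_a: int
    contig_b: str
    strand_b: str
    start_b: int
    end_b: int
    junc_left: int
    junc_right: int

    def __post_init__(self) -> None:
        if not self.read_id:
            raise FormatError("chimeric record with empty read id")
        if self.strand_a not in "+-" or self.strand_b not in "+-":
            raise FormatError(
                f"read {self.read_id!r}: strand must be + or -"
            )
        for start, end, label in (
            (self.start_a, self.end_a, "A"),
            (self.start_b, self.end_b, "B"),
        ):
            if not (0 <= start < end):
                raise FormatError(
                    f"read {self.read_id!r}: segment {label} interval "
                    f"[{start}, {end}) is not a valid half-open interval"
                )


@dataclass(frozen=True)
class SpanRecord:
    """One read aligned to an amplicon: ``[start, end)`` in target coordinates."""

    sample_id: str
    target_id: str
    read_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"span for read {self.read_id!r}: [{self.start}, {self.end}) "
                "is not a valid half-open interval"
            )


# ---------------------------------------------------------------------------
# genome


def read_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased, N kept)."""
    path = Path(path)
    # SeqIO is forgiving about leading junk; reject it explicitly with a line
    # number so malformed files fail loudly.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
    genome = GenomeSequence()
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = str(record.seq)
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# transcripts


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcripts(
    path: str | Path,
    dialect: str = "gtf",
    genome: GenomeSequence | None = None,
) -> list[TranscriptModel]:
    """Read transcript models from GTF or BED12.

    GTF exon lines (1-based closed) are converted to the internal 0-based
    half-open convention; BED12 is consumed natively.  If ``genome`` is
    supplied, exons outside contig bounds raise :class:`FormatError`.
    """
    path = Path(path)
    if dialect == "gtf":
        models = _read_gtf(path)
    elif dialect == "bed12":
        models = _read_bed12(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'gtf' or 'bed12')")
    if not models:
        logger.warning("%s: no transcripts parsed", path)
    if genome is not None:
        for model in models:
            if model.contig not in genome:
                raise FormatError(
                    f"transcript {model.transcript_id!r}: contig "
                    f"{model.contig!r} absent from genome"
                )
            lo, hi = model.span
            if hi > len(genome[model.contig]):
                raise FormatError(
                    f"transcript {model.transcript_id!r}: exon end {hi} exceeds "
                    f"contig {model.contig!r} length {len(genome[model.contig])}"
                )
    return models


def _read_gtf(path: Path) -> list[TranscriptModel]:
    exons: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GTF columns")
            contig, _, feature, start, end, _, strand, _, attr_field = fields
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_field)
            tid = attrs.get("transcript_id")
            if not tid:
                raise FormatError(
                    f"{path}: line {lineno}: exon without transcript_id"
                )
            entry = exons.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "contig": contig,
                    "strand": strand,
                    "exons": [],
                },
            )
            # GTF is 1-based closed; internal is 0-based half-open.
            entry["exons"].append((int(start) - 1, int(end)))
            if tid not in order:
                order.append(tid)
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=exons[tid]["gene_id"],
            contig=exons[tid]["contig"],
            strand=exons[tid]["strand"],
            exons=tuple(sorted(exons[tid]["exons"])),
        )
        for tid in order
    ]


def _read_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 BED columns")
            contig, chrom_start, _, name, _, strand = fields[:6]
            block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(block_sizes) != len(block_starts):
                raise FormatError(
                    f"{path}: line {lineno}: blockSizes/blockStarts mismatch"
                )
            base = int(chrom_start)
            exon_list = tuple(
                (base + bs, base + bs + sz)
                for bs, sz in zip(block_starts, block_sizes)
            )
            models.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    contig=contig,
                    strand=strand,
                    exons=exon_list,
                )
            )
    return models


def write_transcripts_gtf(
    models: Iterable[TranscriptModel], path: str | Path, source: str = "circscreen"
) -> None:
    """Write exon lines in GTF (1-based closed); inverse of :func:`read_transcripts`."""
    with open(path, "w") as fh:
        for model in models:
            for start, end in model.exons:
                attrs = (
                    f'gene_id "{model.gene_id}"; '
                    f'transcript_id "{model.transcript_id}";'
                )
                fh.write(
                    f"{model.contig}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                    f"{model.strand}\t.\t{attrs}\n"
                )


def write_transcripts_bed12(
    models: Iterable[TranscriptModel], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for model in models:
            lo, hi = model.span
            sizes = ",".join(str(e - s) for s, e in model.exons)
            starts = ",".join(str(s - lo) for s, e in model.exons)
            fh.write(
                f"{model.contig}\t{lo}\t{hi}\t{model.transcript_id}\t0\t"
                f"{model.strand}\t{lo}\t{hi}\t0\t{len(model.exons)}\t"
                f"{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# chimeric records


def read_chimeric_records(path: str | Path) -> list[ChimericRecord]:
    """Read the chimeric TSV dialect; malformed lines are rejected and counted."""
    path = Path(path)
    records: list[ChimericRecord] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(CHIMERIC_COLUMNS):
                logger.error(
                    "%s: line %d: expected %d columns, got %d",
                    path, lineno, len(CHIMERIC_COLUMNS), len(fields),
                )
                rejected += 1
                continue
            try:
                records.append(
                    ChimericRecord(
                        read_id=fields[0],
                        contig_a=fields[1],
                        strand_a=fields[2],
                        start_a=int(fields[3]),
                        end_a=int(fields[4]),
                        contig_b=fields[5],
                        strand_b=fields[6],
                        start_b=int(fields[7]),
                        end_b=int(fields[8]),
                        junc_left=int(fields[9]),
                        junc_right=int(fields[10]),
                    )
                )
            except (ValueError, FormatError) as exc:
                logger.error("%s: line %d: %s", path, lineno, exc)
                rejected += 1
    if rejected:
        raise FormatError(
            f"{path}: {rejected} malformed chimeric line(s) rejected "
            f"({len(records)} parsed)"
        )
    return records


def write_chimeric_records(
    records: Iterable[ChimericRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CHIMERIC_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_id, r.contig_a, r.strand_a, r.start_a, r.end_a,
                        r.contig_b, r.strand_b, r.start_b, r.end_b,
                        r.junc_left, r.junc_right,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# span records


def read_span_records(path: str | Path) -> list[SpanRecord]:
    """Read span records from TSV: sample_id, target_id, read_id, start, end."""
    path = Path(path)
    spans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(SPAN_COLUMNS):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(SPAN_COLUMNS)} columns"
                )
            spans.append(
                SpanRecord(
                    sample_id=fields[0],
                    target_id=fields[1],
                    read_id=fields[2],
                    start=int(fields[3]),
                    end=int(fields[4]),
                )
            )
    return spans


def write_span_records(spans: Iterable[SpanRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SPAN_COLUMNS) + "\n")
        for s in spans:
            fh.write(
                f"{s.sample_id}\t{s.target_id}\t{s.read_id}\t{s.start}\t{s.end}\n"
            )


def read_span_records_sam(path: str | Path, sample_id: str) -> list[SpanRecord]:
    """Read spans from a SAM file of reads aligned to amplicon references.

    The reference name is the target id; the span is the reference interval
    consumed by the alignment.  Unmapped and secondary records are skipped.
    """
    import pysam

    spans = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            spans.append(
                SpanRecord(
                    sample_id=sample_id,
                    target_id=aln.reference_name,
                    read_id=aln.query_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                )
            )
    return spans


# ---------------------------------------------------------------------------
# panel targets


def write_targets(targets, fasta_path, bed_path, tsv_path) -> None:
    """Write a panel: amplicon FASTA, BED6 genomic footprint, class/offset TSV.

    BED names are target ids with score 0; the TSV carries class, gene,
    junction offset (empty for linear targets) and source junction id.
    """
    seen: set[str] = set()
    for t in targets:
        if any(c.isspace() for c in t.target_id):
            raise FormatError(f"target id contains whitespace: {t.target_id!r}")
        if t.target_id in seen:
            raise FormatError(f"duplicate target id: {t.target_id!r}")
        seen.add(t.target_id)
    with open(fasta_path, "w") as fh:
        for t in targets:
            fh.write(f">{t.target_id}\n{t.sequence}\n")
    with open(bed_path, "w") as fh:
        for t in targets:
            for start, end in t.footprint:
                fh.write(
                    f"{t.contig}\t{start}\t{end}\t{t.target_id}\t0\t{t.strand}\n"
                )
    with open(tsv_path, "w") as fh:
        fh.write(
            "#target_id\tclass\tgene_id\tcontig\tstrand\tjunction_offset\t"
            "source_junction\tlength\n"
        )
        for t in targets:
            offset = "" if t.junction_offset is None else str(t.junction_offset)
            fh.write(
                f"{t.target_id}\t{t.target_class}\t{t.gene_id}\t{t.contig}\t"
                f"{t.strand}\t{offset}\t{t.source_junction or ''}\t"
                f"{len(t.sequence)}\n"
            )


def read_targets(tsv_path, fasta_path):
    """Read a panel back from the TSV + FASTA pair written by :func:`write_targets`."""
    from .panel import PanelTarget

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    targets = []
    with open(tsv_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            (tid, tclass, gene, contig, strand, offset, source, _length) = (
                line.rstrip("\n").split("\t")
            )
            targets.append(
                PanelTarget(
                    target_id=tid,
                    target_class=tclass,
                    gene_id=gene,
                    sequence=seqs[tid],
                    junction_offset=int(offset) if offset else None,
                    contig=contig,
                    strand=strand,
                    footprint=(),
                    source_junction=source or None,
                )
            )
    return targets
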