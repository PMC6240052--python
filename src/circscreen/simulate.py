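"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration (seed included)
and returns ground truth alongside the simulated data, so every stage of
the pipeline is testable without external downloads.  The generators
emulate: a compact multi-exon genome with canonical GT-AG introns and
planted back-splices; chimeric junction-spanning reads; amplicon panel
libraries (with an RNase-R mode that zeroes linear abundances); and
four-channel barcode image stacks with DAPI nucleus images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import BackspliceJunction
from .io_formats import (
    ChimericRecord,
    FormatError,
    GenomeSequence,
    SpanRecord,
    TranscriptModel,
)
from .panel import Codebook, PanelTarget

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation conditions.

    Defaults produce a 20-gene toy genome with half the genes carrying one
    back-splice, chimeric libraries of 1,000 junction reads, amplicon
    libraries where 80% of reads satisfy the 25-per-side middle rule, and
    512-px image stacks with 500 spots over 20 nuclei.
    """

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (80, 400)
    circ_fraction: float = 0.5
    read_length: int = 100
    depth: int = 1000
    rnase_r: bool = False
    cover_prob: float = 0.8
    image_size: int = 512
    spots_per_image: int = 500
    nuclear_fraction: float = 0.3
    channel_noise: float = 5.0
    spot_amplitude: float = 200.0
    n_nuclei: int = 20
    nucleus_radius: tuple[int, int] = (20, 30)
    min_spot_separation: int = 8

    def __post_init__(self) -> None:
        for name in ("n_genes", "read_length", "depth", "image_size",
                     "spots_per_image", "n_nuclei"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("circ_fraction", "cover_prob", "nuclear_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.intron_length[0] < 4:
            raise ValueError("introns must be >= 4 nt to carry GT...AG")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # one deterministic sub-stream per generator
    seed_seq = np.random.SeedSequence(
        [config.seed, int.from_bytes(stream.encode(), "little") % (2**31)]
    )
    return np.random.default_rng(seed_seq)


# ---------------------------------------------------------------------------
# annotation


def make_toy_annotation(
    config: SimConfig = SimConfig(),
) -> tuple[GenomeSequence, list[TranscriptModel], list[BackspliceJunction]]:
    """Build a toy genome, transcript models and planted back-splices.

    Every intron carries a canonical splice motif (GT...AG in transcript
    orientation, for either strand), and the two bases flanking each
    terminal exon are stamped likewise, so any exon-boundary pair is a
    canonical back-splice candidate.  A seeded subset of genes is
    designated to carry one true back-splice each, chosen from exon pairs
    whose spliced circle is at least 300 nt and whose genomic span
    satisfies the 100,000-nt discovery filter.
    """
    rng = _rng(config, "annotation")
    lo_e, hi_e = config.exons_per_gene
    lo_l, hi_l = config.exon_length
    lo_i, hi_i = config.intron_length
    genes = []
    cursor = 100
    for g in range(config.n_genes):
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for k in range(n_exons):
            length = int(rng.integers(lo_l, hi_l + 1))
            exons.append((pos, pos + length))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(lo_i, hi_i + 1))
        genes.append((g, strand, tuple(exons)))
        cursor = pos + int(rng.integers(100, 300))
    genome_len = cursor + 100
    seq = _BASES[rng.integers(0, 4, size=genome_len)].copy()

    transcripts = []
    for g, strand, exons in genes:
        # splice motifs in transcript orientation at every exon boundary
        donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
        for s, e in exons:
            seq[e] = donor[0]
            seq[e + 1] = donor[1]
            seq[s - 2] = acceptor[0]
            seq[s - 1] = acceptor[1]
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{g}",
                gene_id=f"gene{g}",
                contig="chr1",
                strand=strand,
                exons=exons,
            )
        )
    genome = GenomeSequence()
    genome["chr1"] = "".join(seq)

    n_circ = int(round(config.n_genes * config.circ_fraction))
    designated = sorted(
        int(i) for i in rng.choice(config.n_genes, size=n_circ, replace=False)
    )
    junctions = []
    for g in designated:
        t = transcripts[g]
        pairs = [
            (i, j)
            for i in range(len(t.exons))
            for j in range(i, len(t.exons))
            if sum(e - s for s, e in t.exons[i : j + 1]) >= 300
            and t.exons[j][1] - t.exons[i][0] <= 100_000
        ]
        if not pairs:
            raise FormatError(
                f"gene{g}: no exon pair yields a >= 300 nt circle; widen "
                "exon_length"
            )
        # real circles rarely consume their whole host transcript: prefer
        # pairs leaving spliced room for a linear control on one side
        lengths = [e - s for s, e in t.exons]
        roomy = [
            (i, j)
            for i, j in pairs
            if max(sum(lengths[:i]), sum(lengths[j + 1 :])) >= 440
        ]
        if roomy:
            pairs = roomy
        i, j = pairs[int(rng.integers(len(pairs)))]
        junctions.append(
            BackspliceJunction(
                contig="chr1",
                strand=t.strand,
                donor=t.exons[j][1],
                acceptor=t.exons[i][0],
                count=1,
                motif="GTAG",
                transcript_ids=(t.transcript_id,),
            )
        )
    return genome, transcripts, junctions


# ---------------------------------------------------------------------------
# chimeric reads


def simulate_backsplice_reads(
    transcripts: Sequence[TranscriptModel],
    junctions: Sequence[BackspliceJunction],
    abundances: Sequence[float] | None = None,
    config: SimConfig = SimConfig(),
) -> tuple[list[ChimericRecord], list[SpanRecord], pd.DataFrame]:
    """Simulate junction-spanning chimeric reads plus a linear background.

    Per-junction read counts are multinomial at ``config.depth`` over the
    given abundances (uniform if omitted).  Each read splits into two
    segments flanking the back-splice, consistent with the chimeric TSV
    dialect.  Linear reads are emitted as spans over spliced transcripts
    (target id = transcript id); with ``rnase_r`` on, the linear list is
    empty.  The truth table records the exact per-junction read counts.
    """
    if not junctions:
        raise ValueError("need at least one junction")
    if abundances is None:
        weights = np.ones(len(junctions))
    else:
        weights = np.asarray(abundances, dtype=float)
        if (weights < 0).any():
            raise ValueError("abundances must be >= 0")
    if weights.sum() == 0:
        raise ValueError("total junction abundance is zero")
    rng = _rng(config, "backsplice_reads")
    counts = rng.multinomial(config.depth, weights / weights.sum())
    records = []
    k = 0
    for junction, n in zip(junctions, counts):
        for _ in range(n):
            len_a = int(rng.integers(10, config.read_length - 9))
            len_b = config.read_length - len_a
            records.append(
                ChimericRecord(
                    read_id=f"read{k}",
                    contig_a=junction.contig,
                    strand_a=junction.strand,
                    start_a=junction.donor - len_a,
                    end_a=junction.donor,
                    contig_b=junction.contig,
                    strand_b=junction.strand,
                    start_b=junction.acceptor,
                    end_b=junction.acceptor + len_b,
                    junc_left=junction.acceptor,
                    junc_right=junction.donor,
                )
            )
            k += 1
    linear: list[SpanRecord] = []
    if not config.rnase_r:
        per_tx = max(1, config.depth // max(1, len(transcripts)))
        for t in transcripts:
            total = t.spliced_length()
            if total <= config.read_length:
                continue
            for i in range(per_tx):
                start = int(rng.integers(0, total - config.read_length))
                linear.append(
                    SpanRecord(
                        sample_id="sim",
                        target_id=t.transcript_id,
                        read_id=f"lin{t.transcript_id}_{i}",
                        start=start,
                        end=start + config.read_length,
                    )
                )
    truth = pd.DataFrame(
        {
            "junction_id": [j.junction_id for j in junctions],
            "count": counts,
        }
    )
    return records, linear, truth


# ---------------------------------------------------------------------------
# panel libraries


def simulate_panel_library(
    targets: Sequence[PanelTarget],
    abundances: Mapping[str, float] | Sequence[float],
    config: SimConfig = SimConfig(),
    sample_id: str = "s1",
) -> tuple[list[SpanRecord], int, pd.DataFrame]:
    """Simulate one amplicon sequencing library.

    Reads are distributed over targets multinomially at ``config.depth``.
    A read qualifies under the 25-per-side middle rule with probability
    ``cover_prob``; otherwise it is planted to cover fewer than
    ``min_side`` bases on one side.  With ``rnase_r`` on, linear-target
    abundances are zeroed before sampling.  The truth table stores the
    planted qualifying count per target; the library total equals
    ``config.depth``.
    """
    if isinstance(abundances, Mapping):
        weights = np.array([abundances.get(t.target_id, 0.0) for t in targets])
    else:
        weights = np.asarray(abundances, dtype=float)
    if len(weights) != len(targets):
        raise ValueError("one abundance per target required")
    if (weights < 0).any():
        raise ValueError("abundances must be >= 0")
    weights = weights.copy()
    if config.rnase_r:
        for i, t in enumerate(targets):
            if t.target_class == "linear":
                weights[i] = 0.0
    if weights.sum() == 0:
        raise ValueError("total abundance is zero")
    rng = _rng(config, f"panel_library:{sample_id}")
    counts = rng.multinomial(config.depth, weights / weights.sum())
    min_side = 25
    spans = []
    qualifying = np.zeros(len(targets), dtype=int)
    k = 0
    for i, (target, n) in enumerate(zip(targets, counts)):
        length = len(target.sequence)
        mid = (
            target.junction_offset
            if target.junction_offset is not None
            else length // 2
        )
        rl = min(config.read_length, length)
        lo = max(0, mid + min_side - rl)
        hi = min(mid - min_side, length - rl)
        if hi < lo:
            raise FormatError(
                f"target {target.target_id!r}: read length {rl} cannot "
                "satisfy the middle rule"
            )
        for _ in range(n):
            if rng.random() < config.cover_prob:
                start = int(rng.integers(lo, hi + 1))
                end = min(length, start + rl)
                qualifying[i] += 1
            else:
                # cover at most min_side - 1 bases left of the middle
                start = mid - int(rng.integers(0, min_side))
                end = min(length, start + rl)
            spans.append(
                SpanRecord(
                    sample_id=sample_id,
                    target_id=target.target_id,
                    read_id=f"{sample_id}_r{k}",
                    start=start,
                    end=end,
                )
            )
            k += 1
    truth = pd.DataFrame(
        {
            "target_id": [t.target_id for t in targets],
            "class": [t.target_class for t in targets],
            "planted_reads": counts,
            "qualifying_reads": qualifying,
        }
    )
    return spans, config.depth, truth


# ---------------------------------------------------------------------------
# in situ image stacks


def simulate_insitu_stack(
    codebook: Codebook,
    per_target_counts: Mapping[str, int],
    nuclear_fractions: Mapping[str, float],
    config: SimConfig = SimConfig(),
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a four-channel barcode image stack with a DAPI image.

    Nuclei are disks; each spot is placed inside a nucleus or in the
    cytoplasm according to its target's planted nuclear fraction, at least
    ``min_spot_separation`` px from every other spot.  Per cycle, the
    channel of the spot's barcode base receives a Gaussian blob of
    amplitude ``spot_amplitude``; all channels receive truncated-Gaussian
    background of scale ``channel_noise``.  Returns the stack with shape
    (n_cycles, 4, H, W), the DAPI image, and a per-spot truth table.
    """
    if not codebook:
        raise ValueError("empty codebook")
    n_cycles = codebook.barcode_length
    size = config.image_size
    rng = _rng(config, "insitu")
    to_barcode = codebook.target_to_barcode()
    for target in per_target_counts:
        if target not in to_barcode:
            raise ValueError(f"target {target!r} not in codebook")

    # nuclei as disks, centers kept apart by the sum of radii
    margin = config.nucleus_radius[1] + 5
    centers: list[tuple[int, int, int]] = []
    attempts = 0
    while len(centers) < config.n_nuclei:
        attempts += 1
        if attempts > 20_000:
            raise FormatError(
                f"cannot place {config.n_nuclei} nuclei in a "
                f"{size}x{size} image"
            )
        r = int(rng.integers(config.nucleus_radius[0], config.nucleus_radius[1] + 1))
        cy = int(rng.integers(margin, size - margin))
        cx = int(rng.integers(margin, size - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 4) ** 2
               for y, x, rr in centers):
            centers.append((cy, cx, r))
    yy, xx = np.mgrid[0:size, 0:size]
    dapi = np.zeros((size, size), dtype=float)
    nucleus_mask = np.zeros((size, size), dtype=bool)
    for cy, cx, r in centers:
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        dapi[disk] = 100.0
        nucleus_mask |= disk

    # spot placement honoring compartment and separation
    total_spots = sum(per_target_counts.values())
    sep2 = config.min_spot_separation ** 2
    placed: list[tuple[int, int]] = []
    rows = []
    spot_id = 0
    for target, n in sorted(per_target_counts.items()):
        frac = nuclear_fractions.get(target, config.nuclear_fraction)
        barcode = to_barcode[target]
        for _ in range(n):
            nuclear = rng.random() < frac
            for attempt in range(10_000):
                if nuclear:
                    cyi, cxi, r = centers[int(rng.integers(len(centers)))]
                    ang = rng.random() * 2 * np.pi
                    rad = rng.random() ** 0.5 * max(1, r - 4)
                    y = int(round(cyi + rad * np.sin(ang)))
                    x = int(round(cxi + rad * np.cos(ang)))
                else:
                    y = int(rng.integers(10, size - 10))
                    x = int(rng.integers(10, size - 10))
                    # stay clear of nuclei (with a safety rim)
                    if nucleus_mask[
                        max(0, y - 4) : y + 5, max(0, x - 4) : x + 5
                    ].any():
                        continue
                if all((y - py) ** 2 + (x - px) ** 2 > sep2 for py, px in placed):
                    break
            else:
                raise FormatError(
                    f"cannot place {total_spots} spots at separation "
                    f"{config.min_spot_separation} in a {size}x{size} image"
                )
            placed.append((y, x))
            rows.append(
                {
                    "spot_id": spot_id,
                    "x": x,
                    "y": y,
                    "target_id": target,
                    "barcode": barcode,
                    "compartment": "nuclear" if nuclear else "cytoplasmic",
                }
            )
            spot_id += 1
    truth = pd.DataFrame(
        rows,
        columns=["spot_id", "x", "y", "target_id", "barcode", "compartment"],
    )

    stack = np.zeros((n_cycles, 4, size, size), dtype=float)
    if config.channel_noise > 0:
        noise = rng.normal(0, config.channel_noise, size=stack.shape)
        stack += np.clip(noise, 0, None)  # truncated-Gaussian background
    blob = _gaussian_blob(sigma=1.2, radius=4)
    channel_index = {b: i for i, b in enumerate("ACGT")}
    for row in rows:
        y, x = row["y"], row["x"]
        for cycle, base in enumerate(row["barcode"]):
            amp = config.spot_amplitude
            if config.channel_noise > 0:
                amp *= float(np.clip(rng.normal(1.0, 0.1), 0.5, 1.5))
            _add_blob(stack[cycle, channel_index[base]], y, x, amp * blob)
    return stack, dapi, truth


def _gaussian_blob(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma ** 2))
    return g


def _add_blob(image: np.ndarray, y: int, x: int, blob: np.ndarray) -> None:
    r = blob.shape[0] // 2
    h, w = image.shape
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    image[y0:y1, x0:x1] += blob[
        r - (y - y0) : r + (y1 - y), r - (x - x0) : r + (x1 - x)
    ]


def write_insitu_tiffs(stack: np.ndarray, dapi: np.ndarray, stack_path, dapi_path) -> None:
    """Write the stack as a multi-page TIFF (page order: cycle-major, then
    channel A,C,G,T) and the DAPI image as a single-page TIFF."""
    import tifffile

    n_cycles, n_channels, h, w = stack.shape
    pages = stack.reshape(n_cycles * n_channels, h, w).astype(np.float32)
    tifffile.imwrite(stack_path, pages)
    tifffile.imwrite(dapi_path, dapi.astype(np.float32))


def read_insitu_tiffs(stack_path, dapi_path, n_cycles: int = 4):
    import tifffile

    pages = tifffile.imread(stack_path)
    if pages.ndim != 3 or pages.shape[0] % 4 != 0:
        raise FormatError("stack TIFF must hold n_cycles x 4 pages")
    stack = pages.reshape(pages.shape[0] // 4, 4, *pages.shape[1:])
    dapi = tifffile.imread(dapi_path)
    return np.asarray(stack, dtype=float), np.asarray(dapi, dtype=float)
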