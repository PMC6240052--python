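"""Decoding of barcode-based in situ sequencing signals.

Rolling-circle products (RCPs) appear as bright spots in a general-stain
image; each sequencing-by-ligation cycle produces four channel images
(A, C, G, T).  Per cycle the called base is the channel with the highest
intensity and its quality is max / sum over the four channels, which
ranges from 0.25 (all channels equal — pure noise) to 1 (one channel
only).  A transcript's quality is the minimum of its per-base qualities;
decoded 4-nt barcodes above the quality threshold are matched exactly
against the codebook, and each spot is assigned to the nuclear or
cytoplasmic compartment by membership in the DAPI nucleus mask.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat
from skimage.segmentation import watershed

from .panel import Codebook

logger = logging.getLogger(__name__)

CHANNELS = "ACGT"


@dataclass(frozen=True)
class DecodeParams:
    """Decoding knobs.

    ``quality_threshold`` defaults to 0.45, the midpoint of the 0.40–0.55
    band of practical interest; valid qualities live in [0.25, 1].
    """

    n_cycles: int = 4
    quality_threshold: float = 0.45
    tophat_radius: int = 5
    spot_min_intensity: float = 50.0
    min_spot_separation: int = 5
    extraction_window: int = 3

    def __post_init__(self) -> None:
        if not (0.25 <= self.quality_threshold <= 1.0):
            raise ValueError("quality_threshold must lie in [0.25, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass(frozen=True)
class RcpSignal:
    """One rolling-circle product and everything decoded from it."""

    spot_id: int
    x: float
    y: float
    intensities: tuple[tuple[float, ...], ...]  # n_cycles x 4, order A,C,G,T
    sequence: str = ""
    qualities: tuple[float, ...] = ()
    quality: float = 0.0
    compartment: str = "unassigned"
    target_id: str | None = None


@dataclass
class DecodeResult:
    signals: list[RcpSignal]
    counts: dict[str, int]
    n_rejected_quality: int
    n_unexpected: int
    unexpected_sequences: Counter = field(default_factory=Counter)


# ---------------------------------------------------------------------------
# spot detection


def detect_spots(
    image: np.ndarray, params: DecodeParams = DecodeParams()
) -> list[tuple[float, float]]:
    """Detect RCP spots in a general-stain image.

    White top-hat enhancement (disk of ``tophat_radius``), global threshold
    at ``spot_min_intensity``, then watershed to split touching blobs with
    one intensity-weighted centroid per region.  Returns (x, y) positions
    in pixel coordinates (x = column, y = row).  Deterministic.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={image.ndim}")
    enhanced = white_tophat(image, footprint=disk(params.tophat_radius))
    mask = enhanced >= params.spot_min_intensity
    if not mask.any():
        return []
    peaks = peak_local_max(
        enhanced,
        min_distance=params.min_spot_separation,
        threshold_abs=params.spot_min_intensity,
        labels=mask,
    )
    if len(peaks) == 0:
        return []
    markers = np.zeros(image.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-enhanced, markers=markers, mask=mask)
    out = []
    for region in regionprops(labels, intensity_image=enhanced):
        cy, cx = region.centroid_weighted
        out.append((float(cx), float(cy)))
    out.sort()
    return out


def extract_intensities(
    stack: np.ndarray,
    positions: Sequence[tuple[float, float]],
    params: DecodeParams = DecodeParams(),
) -> list[RcpSignal]:
    """Mean intensity in a small window per (cycle, channel) at each spot.

    ``stack`` has shape (n_cycles, 4, H, W) with channels in A, C, G, T
    order.  The window is ``extraction_window`` pixels square, centered on
    the rounded detection (robust to 1-px jitter).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4 or stack.shape[1] != 4:
        raise ValueError("stack must have shape (n_cycles, 4, H, W)")
    n_cycles, _, h, w = stack.shape
    half = params.extraction_window // 2
    signals = []
    for i, (x, y) in enumerate(positions):
        r, c = int(round(y)), int(round(x))
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        per_cycle = tuple(
            tuple(float(stack[cy, ch, r0:r1, c0:c1].mean()) for ch in range(4))
            for cy in range(n_cycles)
        )
        signals.append(RcpSignal(spot_id=i, x=x, y=y, intensities=per_cycle))
    return signals


# ---------------------------------------------------------------------------
# base calling


def call_base(intensities: Sequence[float]) -> tuple[str, float]:
    """Call one base from a four-channel intensity vector.

    The base is the highest-intensity channel; quality is max / sum, which
    is 1 for a one-hot vector and 0.25 when all four channels are equal.
    Ties break by channel order A > C > G > T.  An all-zero vector calls
    "N" with quality 0.25.
    """
    vec = np.asarray(intensities, dtype=float)
    if vec.shape != (4,):
        raise ValueError("expected exactly 4 channel intensities")
    if (vec < 0).any():
        raise ValueError("channel intensities must be >= 0")
    total = vec.sum()
    if total == 0:
        return "N", 0.25
    idx = int(np.argmax(vec))  # argmax takes the first max: A > C > G > T
    return CHANNELS[idx], float(vec[idx] / total)


def decode_rcp(signal: RcpSignal, params: DecodeParams = DecodeParams()) -> RcpSignal:
    """Decode one RCP: per-cycle base calls, transcript quality = min."""
    if len(signal.intensities) != params.n_cycles:
        raise ValueError(
            f"spot {signal.spot_id}: expected {params.n_cycles} cycles, "
            f"got {len(signal.intensities)}"
        )
    bases, quals = [], []
    for vec in signal.intensities:
        base, q = call_base(vec)
        bases.append(base)
        quals.append(q)
    return replace(
        signal,
        sequence="".join(bases),
        qualities=tuple(quals),
        quality=min(quals),
    )


def filter_and_assign(
    signals: Iterable[RcpSignal],
    codebook: Codebook,
    params: DecodeParams = DecodeParams(),
) -> DecodeResult:
    """Quality-filter decoded signals and match barcodes to targets.

    Signals below ``quality_threshold`` are dropped; surviving sequences
    are matched exactly against the codebook (no mismatch rescue) and
    non-matching sequences tallied as unexpected.
    """
    if codebook and codebook.barcode_length != params.n_cycles:
        raise ValueError(
            f"codebook barcodes are {codebook.barcode_length} nt but "
            f"n_cycles = {params.n_cycles}"
        )
    kept: list[RcpSignal] = []
    counts: dict[str, int] = {t: 0 for t in codebook.values()}
    unexpected: Counter = Counter()
    n_rejected = 0
    for s in signals:
        if not s.sequence:
            s = decode_rcp(s, params)
        if s.quality < params.quality_threshold:
            n_rejected += 1
            continue
        target = codebook.get(s.sequence)
        if target is None:
            unexpected[s.sequence] += 1
            kept.append(replace(s, target_id=None))
            continue
        counts[target] += 1
        kept.append(replace(s, target_id=target))
    return DecodeResult(
        signals=kept,
        counts=counts,
        n_rejected_quality=n_rejected,
        n_unexpected=sum(unexpected.values()),
        unexpected_sequences=unexpected,
    )


# ---------------------------------------------------------------------------
# nuclei and compartments


def segment_nuclei(
    dapi: np.ndarray,
    params: DecodeParams = DecodeParams(),
    sigma: float = 2.0,
    min_area: int = 20,
) -> np.ndarray:
    """Segment nuclei from a DAPI image into a label mask.

    Gaussian smoothing, Otsu threshold, hole filling, then a watershed on
    the distance transform to split touching nuclei.  Background is 0,
    nuclei are labeled 1..K.  A blank image yields an all-zero mask.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={dapi.ndim}")
    if np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=int)
    smoothed = gaussian(dapi, sigma=sigma, preserve_range=True)
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=int)
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=5, labels=mask, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers=markers, mask=mask)
    # drop specks, then relabel densely for stable ids
    sizes = np.bincount(labels.ravel())
    for lbl in np.nonzero(sizes < min_area)[0]:
        if lbl:
            labels[labels == lbl] = 0
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    values = np.unique(labels)
    lut = np.zeros(values.max() + 1, dtype=int)
    nxt = 1
    for v in values:
        if v == 0:
            continue
        lut[v] = nxt
        nxt += 1
    return lut[labels]


def assign_compartment(signal: RcpSignal, mask: np.ndarray) -> str:
    """Nuclear iff the mask at the rounded spot pixel is > 0, else cytoplasmic.

    Out-of-bounds positions stay unassigned with a warning.  Nuclearity is
    mask membership only; with widefield imaging some true cytoplasmic
    signals overlying a nucleus will be called nuclear.
    """
    r, c = int(round(signal.y)), int(round(signal.x))
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        logger.warning(
            "spot %d at (%.1f, %.1f) outside image bounds", signal.spot_id,
            signal.x, signal.y,
        )
        return "unassigned"
    return "nuclear" if mask[r, c] > 0 else "cytoplasmic"


def assign_compartments(
    signals: Iterable[RcpSignal], mask: np.ndarray
) -> list[RcpSignal]:
    return [
        replace(s, compartment=assign_compartment(s, mask)) for s in signals
    ]


def nuclear_ratio(signals: Iterable[RcpSignal]) -> dict[str, float]:
    """Per-target fraction of assigned signals inside nuclei.

    Targets with zero assigned signals are excluded (undefined ratio).
    """
    nuc: Counter = Counter()
    tot: Counter = Counter()
    for s in signals:
        if s.target_id is None or s.compartment == "unassigned":
            continue
        tot[s.target_id] += 1
        if s.compartment == "nuclear":
            nuc[s.target_id] += 1
    return {t: nuc[t] / tot[t] for t in tot}


# ---------------------------------------------------------------------------
# pipeline over an image stack


def register_translation(
    reference: np.ndarray, moving: np.ndarray
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rigid-translation alignment of one cycle image onto a reference.

    Phase cross-correlation at integer precision; returns the shifted
    image and the applied (row, col) shift.  Intended for synthetic data
    where cycles differ by pure translation; real multi-cycle registration
    is assumed done upstream.
    """
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(reference, moving)
    shifted = ndimage.shift(moving, shift, order=1, mode="nearest")
    return shifted, (float(shift[0]), float(shift[1]))


def decode_stack(
    stack: np.ndarray,
    dapi: np.ndarray,
    codebook: Codebook,
    params: DecodeParams = DecodeParams(),
    general_stain: np.ndarray | None = None,
) -> tuple[DecodeResult, dict[str, float], np.ndarray]:
    """Full decode: spots -> intensities -> base calls -> barcode match ->
    compartment.  The general stain defaults to the sum of the four
    channels of the first cycle.  Returns (result, nuclear ratios, mask).
    """
    stack = np.asarray(stack, dtype=float)
    if general_stain is None:
        general_stain = stack[0].sum(axis=0)
    positions = detect_spots(general_stain, params)
    signals = extract_intensities(stack, positions, params)
    signals = [decode_rcp(s, params) for s in signals]
    result = filter_and_assign(signals, codebook, params)
    mask = segment_nuclei(dapi, params)
    result.signals = assign_compartments(result.signals, mask)
    ratios = nuclear_ratio(result.signals)
    return result, ratios, mask


def write_signals(signals: Iterable[RcpSignal], path) -> None:
    with open(path, "w") as fh:
        fh.write("#spot_id\tx\ty\tsequence\tquality\ttarget_id\tcompartment\n")
        for s in signals:
            fh.write(
                f"{s.spot_id}\t{s.x:.2f}\t{s.y:.2f}\t{s.sequence}\t"
                f"{s.quality:.4f}\t{s.target_id or 'unexpected'}\t"
                f"{s.compartment}\n"
            )
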