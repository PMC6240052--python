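"""Junction-aware read counting, normalization, circ/linear ratios,
sample clustering and the qPCR ΔΔCt utility.

The counting rule: a read supports a circular (or negative-control)
target only if it maps at least ``min_side`` bases on *each* side of the
back-splice junction — 50 bases over the middle of the amplicon under
the defaults.  Linear targets use the same 50-consecutive-base rule
around the amplicon midpoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .io_formats import SpanRecord
from .panel import PanelTarget

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    min_span_total: int = 50
    min_side: int = 25
    pseudocount_for_log: float = 1.0

    def __post_init__(self) -> None:
        if self.min_span_total <= 0 or self.min_side <= 0:
            raise ValueError("span rule lengths must be > 0")
        if self.pseudocount_for_log <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class CountMatrix:
    """Targets x samples counts with per-sample library totals.

    ``normalized[t, s] = raw[t, s] / library_total[s]`` where the library
    total is the total number of reads generated for the sample (which may
    exceed the column sum — off-target reads still count toward it).
    """

    raw: pd.DataFrame
    library_totals: pd.Series
    normalized: pd.DataFrame | None = None
    target_classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.raw.values < 0).any():
            raise ValueError("raw counts must be >= 0")
        col_sums = self.raw.sum(axis=0)
        for sample in self.raw.columns:
            if sample not in self.library_totals.index:
                raise ValueError(f"no library total for sample {sample!r}")
            if self.library_totals[sample] < col_sums[sample]:
                raise ValueError(
                    f"library total for {sample!r} "
                    f"({self.library_totals[sample]}) is below its column "
                    f"sum ({col_sums[sample]})"
                )


def read_spans_target(
    span: SpanRecord, target: PanelTarget, params: QuantParams = QuantParams()
) -> bool:
    """Does this aligned span support the target under the middle rule?

    Circ/negative targets: the span must cover at least ``min_side`` bases
    on each side of the junction offset.  Linear targets: the same rule
    around the amplicon midpoint ``floor(length / 2)``, i.e. 50 consecutive
    mapped bases over the middle under defaults.
    """
    if span.end > len(target.sequence):
        raise ValueError(
            f"span [{span.start}, {span.end}) exceeds target "
            f"{target.target_id!r} length {len(target.sequence)}"
        )
    if target.junction_offset is not None:
        mid = target.junction_offset
    else:
        mid = len(target.sequence) // 2
    return span.start <= mid - params.min_side and span.end >= mid + params.min_side


def count_reads(
    spans: Iterable[SpanRecord],
    targets: Sequence[PanelTarget],
    params: QuantParams = QuantParams(),
    samples: Sequence[str] | None = None,
) -> CountMatrix:
    """Count distinct qualifying read ids per (target, sample).

    Spans that fail the middle rule, or reference targets outside the
    panel, are tallied and logged but not counted.  If ``samples`` is
    given, a span with an unknown sample id is an error; otherwise the
    sample set is inferred from the spans.
    """
    by_id = {t.target_id: t for t in targets}
    spans = list(spans)
    if samples is None:
        samples = sorted({s.sample_id for s in spans})
    else:
        samples = list(samples)
        known = set(samples)
        for s in spans:
            if s.sample_id not in known:
                raise ValueError(f"unknown sample id {s.sample_id!r}")
    seen: dict[tuple[str, str], set[str]] = {}
    unmatched = 0
    for s in spans:
        target = by_id.get(s.target_id)
        if target is None or not read_spans_target(s, target, params):
            unmatched += 1
            continue
        seen.setdefault((s.target_id, s.sample_id), set()).add(s.read_id)
    if unmatched:
        logger.info("%d span(s) did not qualify for any target", unmatched)
    raw = pd.DataFrame(
        0, index=[t.target_id for t in targets], columns=samples, dtype=int
    )
    for (tid, sid), reads in seen.items():
        raw.loc[tid, sid] = len(reads)
    classes = pd.Series(
        {t.target_id: t.target_class for t in targets}, name="class"
    )
    totals = raw.sum(axis=0)
    return CountMatrix(raw=raw, library_totals=totals, target_classes=classes)


def normalize(
    matrix: CountMatrix, library_totals: Mapping[str, float] | None = None
) -> CountMatrix:
    """Divide each count by the total reads generated for its sample."""
    totals = (
        pd.Series(library_totals)
        if library_totals is not None
        else matrix.library_totals
    )
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"non-positive library total for sample(s) {bad}")
    out = CountMatrix(
        raw=matrix.raw,
        library_totals=totals,
        target_classes=matrix.target_classes,
    )
    out.normalized = matrix.raw.div(totals, axis=1)
    return out


def relative_circ_expression(circ: float, linear: float) -> float:
    """circ / (circ + linear); NaN (undefined) when both are zero.

    0.5 marks equal circular and linear expression; 1.0 is the RNase-R
    expectation (linear signal lost, circular preserved).
    """
    if circ < 0 or linear < 0:
        raise ValueError("counts must be >= 0")
    if circ + linear == 0:
        return math.nan
    return circ / (circ + linear)


def circ_ratio_table(
    matrix: CountMatrix,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-gene circ/(circ+linear) ratios across samples.

    ``pairs`` is (circ_target_id, linear_target_id) per gene; undefined
    ratios (0/0) come back as NaN and are excluded from summaries.
    """
    rows = {}
    for circ_id, linear_id in pairs:
        rows[circ_id] = [
            relative_circ_expression(
                float(matrix.raw.loc[circ_id, s]),
                float(matrix.raw.loc[linear_id, s]),
            )
            for s in matrix.raw.columns
        ]
    return pd.DataFrame(rows, index=matrix.raw.columns).T


def log_counts(
    counts: pd.DataFrame | pd.Series | np.ndarray,
    params: QuantParams = QuantParams(),
):
    """log10(count + pseudocount); zero counts map to 0 under the default."""
    return np.log10(counts + params.pseudocount_for_log)


def compare_panel_vs_rnaseq(
    panel_counts: pd.Series,
    rnaseq_counts: pd.Series,
    params: QuantParams = QuantParams(),
) -> tuple[pd.DataFrame, float]:
    """Pair per-target panel and RNA-seq counts; R^2 on log10(x+1) values.

    Both count vectors must come from the same amplicon reference universe
    (RNA-seq reads aligned to the panel target sequences and counted with
    the same middle rule).  Returns the paired table and squared Pearson
    correlation, symmetric in its inputs.
    """
    shared = panel_counts.index.intersection(rnaseq_counts.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared targets; need at least 3"
        )
    table = pd.DataFrame(
        {
            "panel": panel_counts.loc[shared].astype(float),
            "rnaseq": rnaseq_counts.loc[shared].astype(float),
            "log_panel": log_counts(panel_counts.loc[shared].astype(float), params),
            "log_rnaseq": log_counts(rnaseq_counts.loc[shared].astype(float), params),
        }
    )
    r, _ = pearsonr(table["log_panel"], table["log_rnaseq"])
    return table, float(r ** 2)


def cluster_samples(
    matrix: CountMatrix,
    metric: str = "correlation",
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples over all targets.

    Distance is 1 - Pearson correlation between sample profiles (scale
    robust) with average linkage by default.  Returns the scipy linkage
    matrix and the leaf order as sample ids.
    """
    data = matrix.normalized if matrix.normalized is not None else matrix.raw
    if data.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    profiles = data.T.values.astype(float)
    if metric == "correlation":
        corr = np.corrcoef(profiles)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        condensed = squareform(dist, checks=False)
    else:
        from scipy.spatial.distance import pdist

        condensed = pdist(profiles, metric=metric)
    linkage = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(linkage)
    labels = [data.columns[i] for i in order]
    return linkage, labels


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def ddct_fold(
    ct_target: float,
    ct_reference_gene: float,
    ct_calibrator_target: float,
    ct_calibrator_reference: float,
) -> float:
    """Relative expression by the ΔΔCt method.

    Ct values are first normalized to a reference gene (e.g. beta-actin),
    then to a calibrator target; fold change is 2^-ΔΔCt.
    """
    for ct in (ct_target, ct_reference_gene, ct_calibrator_target,
               ct_calibrator_reference):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference_gene) - (
        ct_calibrator_target - ct_calibrator_reference
    )
    return 2.0 ** (-ddct)
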