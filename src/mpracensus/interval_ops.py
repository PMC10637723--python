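"""Interval algebra over ChIP-seq peak sets.

Merging of per-library peak calls into a consensus peak set, cross-library
sharing fractions, Jaccard similarity between binding profiles, genomic
context annotation of peak summits, promoter-recurrence across cell types,
activity-by-contact (ABC) enhancer-gene linking, and chromatin-state
composition of peak regions.

All coordinates are 0-based half-open internally (BED convention).
Bookended intervals ([0,100) and [100,200)) share no base and do not merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "MergedPeak",
    "GeneModel",
    "AbcConnection",
    "merge_peaks",
    "fraction_shared",
    "jaccard",
    "annotate_context",
    "recurrent_promoter_genes",
    "link_abc",
    "overlap_composition",
]


class IntervalError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise IntervalError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak with its summit and a strength score."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise IntervalError(
                f"summit {self.summit} outside [{self.interval.start}, "
                f"{self.interval.end})"
            )


@dataclass(frozen=True)
class MergedPeak:
    interval: GenomicInterval
    members: Mapping[str, bool]

    def __post_init__(self) -> None:
        if not any(self.members.values()):
            raise IntervalError("merged peak with no contributing source")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: a TSS with strand and the exons of one transcript."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        exs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
            if s2 < e1:
                raise IntervalError(
                    f"{self.gene_id}: exons overlap within transcript"
                )

    @property
    def span(self) -> tuple[int, int] | None:
        if not self.exons:
            return None
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def tts(self) -> int | None:
        """Transcript 3' end (the end opposite the TSS)."""
        span = self.span
        if span is None:
            return None
        return span[1] if self.strand == "+" else span[0]


@dataclass(frozen=True)
class AbcConnection:
    element: GenomicInterval
    gene_id: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise IntervalError("ABC score must be >= 0")


def _iv(x) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


def _merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Self-merge into maximal non-overlapping intervals (>= 1 bp overlap)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def merge_peaks(
    peak_sets: Sequence[tuple[str, Sequence[Peak]]]
) -> list[MergedPeak]:
    """Transitive closure of >=1 bp overlaps across all peak sets.

    Each merged region records which input labels contributed at least one
    peak (the member flags).  Output is sorted by (chrom, start).
    """
    labels = [label for label, _ in peak_sets]
    tagged: list[tuple[GenomicInterval, str]] = []
    for label, peaks in peak_sets:
        for p in peaks:
            tagged.append((_iv(p), label))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    merged: list[MergedPeak] = []
    cur: GenomicInterval | None = None
    cur_members: dict[str, bool] = {}
    for iv, label in tagged:
        if cur is not None and cur.chrom == iv.chrom and iv.start < cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            cur_members[label] = True
        else:
            if cur is not None:
                merged.append(MergedPeak(cur, dict(cur_members)))
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
            cur_members = {lab: False for lab in labels}
            cur_members[label] = True
    if cur is not None:
        merged.append(MergedPeak(cur, dict(cur_members)))
    return merged


def fraction_shared(
    peak_sets: Sequence[tuple[str, Sequence[Peak]]]
) -> dict[str, float | None]:
    """Per label: fraction of its peaks overlapping any other label's peaks.

    A peak overlapping several peaks of another set counts once.  Empty
    input sets yield ``None`` (undefined fraction).
    """
    if len(peak_sets) < 2:
        raise IntervalError("fraction_shared requires at least two peak sets")
    out: dict[str, float | None] = {}
    for i, (label, peaks) in enumerate(peak_sets):
        if not peaks:
            out[label] = None
            continue
        others = _merge_intervals(
            _iv(p) for j, (_, ps) in enumerate(peak_sets) if j != i for p in ps
        )
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in others:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        shared = 0
        for p in peaks:
            iv = _iv(p)
            shared += any(
                iv.overlap(o) > 0 for o in by_chrom.get(iv.chrom, ())
            )
        out[label] = shared / len(peaks)
    return out


def _total_len(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def _intersection_len(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Total intersected bp between two self-merged, sorted interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom == y.chrom:
            total += max(0, min(x.end, y.end) - max(x.start, y.start))
            if (x.chrom, x.end) <= (y.chrom, y.end):
                i += 1
            else:
                j += 1
        elif (x.chrom, x.end) < (y.chrom, y.end):
            i += 1
        else:
            j += 1
    return total


def jaccard(
    set_a: Sequence[Peak | GenomicInterval],
    set_b: Sequence[Peak | GenomicInterval],
    resize_halfwidth: int | None = None,
) -> float:
    """Jaccard similarity: intersection bp / union bp after self-merge.

    With ``resize_halfwidth`` every interval is first replaced by
    center +/- halfwidth (center = floor((start+end)/2)), mimicking
    comparisons of equal-width binding regions.  Two empty sets give 0.
    """

    def prepare(items) -> list[GenomicInterval]:
        ivs = [_iv(x) for x in items]
        if resize_halfwidth is not None:
            ivs = [
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.center() - resize_halfwidth),
                    iv.center() + resize_halfwidth,
                )
                for iv in ivs
            ]
        return _merge_intervals(ivs)

    a = prepare(set_a)
    b = prepare(set_b)
    inter = _intersection_len(a, b)
    union = _total_len(a) + _total_len(b) - inter
    return inter / union if union else 0.0


def annotate_context(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 1000,
    tts_halfwidth: int = 1000,
) -> list[str]:
    """Genomic context label per peak summit.

    Priority: promoter > exon > intron > TTS > intergenic.  The promoter is
    TSS +/- ``promoter_halfwidth`` (bounds inclusive); exon/intron by summit
    containment in the transcript; TTS-proximal within ``tts_halfwidth`` of
    the transcript 3' end.
    """
    labels = []
    for p in peaks:
        s = p.summit
        chrom = p.interval.chrom
        label = "intergenic"
        best = 5
        for g in genes:
            if g.chrom != chrom:
                continue
            if abs(s - g.tss) <= promoter_halfwidth:
                rank, cand = 1, "promoter"
            elif g.exons and any(e0 <= s < e1 for e0, e1 in g.exons):
                rank, cand = 2, "exon"
            elif g.span and g.span[0] <= s < g.span[1]:
                rank, cand = 3, "intron"
            elif g.tts is not None and abs(s - g.tts) <= tts_halfwidth:
                rank, cand = 4, "TTS"
            else:
                continue
            if rank < best:
                best, label = rank, cand
        labels.append(label)
    return labels


def recurrent_promoter_genes(
    peak_sets: Sequence[tuple[str, Sequence[Peak]]],
    genes: Sequence[GeneModel],
    k: int,
    promoter_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Genes whose promoter window holds >=1 summit in >= k labels.

    Returns the per-label incidence matrix (bool columns, one per label)
    with an ``n_sets`` count column, restricted to genes reaching ``k``.
    """
    labels = [label for label, _ in peak_sets]
    if k > len(labels):
        warnings.warn(
            f"recurrence threshold k={k} exceeds the number of peak sets "
            f"({len(labels)}); result is empty",
            stacklevel=2,
        )
    incidence = pd.DataFrame(False, index=[g.gene_id for g in genes], columns=labels)
    for label, peaks in peak_sets:
        summits = {}
        for p in peaks:
            summits.setdefault(p.interval.chrom, []).append(p.summit)
        for g in genes:
            hit = any(
                abs(s - g.tss) <= promoter_halfwidth
                for s in summits.get(g.chrom, ())
            )
            if hit:
                incidence.loc[g.gene_id, label] = True
    incidence["n_sets"] = incidence[labels].sum(axis=1)
    out = incidence[incidence["n_sets"] >= k].copy()
    out.index.name = "gene_id"
    return out.sort_values(["n_sets", "gene_id"], ascending=[False, True])


def link_abc(
    peaks: Sequence[Peak],
    connections: Sequence[AbcConnection],
    min_score: float = 0.015,
    min_overlap: int = 50,
    top_genes: int = 3,
) -> pd.DataFrame:
    """Peak-to-gene links through ABC element-gene connections.

    A link requires element/peak overlap >= ``min_overlap`` bp and ABC
    score >= ``min_score``; per peak, up to ``top_genes`` genes are kept by
    descending score, ties broken by gene_id lexical order.
    """
    rows = []
    for idx, p in enumerate(peaks):
        iv = _iv(p)
        cands = []
        for c in connections:
            ov = iv.overlap(c.element)
            if ov >= min_overlap and c.score >= min_score:
                cands.append((c, ov))
        best: dict[str, tuple[AbcConnection, int]] = {}
        for c, ov in cands:
            cur = best.get(c.gene_id)
            if cur is None or c.score > cur[0].score:
                best[c.gene_id] = (c, ov)
        ranked = sorted(
            best.values(), key=lambda t: (-t[0].score, t[0].gene_id)
        )[:top_genes]
        for c, ov in ranked:
            rows.append(
                {
                    "peak_index": idx,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "gene_id": c.gene_id,
                    "abc_score": c.score,
                    "overlap_bp": ov,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_index",
            "chrom",
            "start",
            "end",
            "gene_id",
            "abc_score",
            "overlap_bp",
        ],
    )


def overlap_composition(
    peaks: Sequence[Peak | GenomicInterval],
    segmentation: Sequence[tuple[GenomicInterval, str]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Chromatin-state composition of peak bp and of the genome.

    ``segmentation`` is a non-overlapping labelled interval set; bases not
    covered by it (up to the per-chromosome extent of segmentation and
    peaks) are labelled ``unannotated``.  Returns (fractions over merged
    peak bp, fractions over genome bp); each vector sums to 1.
    """
    merged = _merge_intervals(_iv(p) for p in peaks)
    seg_by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, label in segmentation:
        seg_by_chrom.setdefault(iv.chrom, []).append((iv, label))
    for chrom, items in seg_by_chrom.items():
        items.sort(key=lambda t: t[0].start)
        for (a, _), (b, _) in zip(items, items[1:]):
            if b.start < a.end:
                raise IntervalError(f"segmentation overlaps itself on {chrom}")

    extent: dict[str, int] = {}
    for iv in merged:
        extent[iv.chrom] = max(extent.get(iv.chrom, 0), iv.end)
    for chrom, items in seg_by_chrom.items():
        extent[chrom] = max(extent.get(chrom, 0), items[-1][0].end)

    # full labelled tiling per chromosome, gaps as "unannotated"
    tiling: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, stop in extent.items():
        pieces = []
        cursor = 0
        for iv, label in seg_by_chrom.get(chrom, ()):
            if iv.start > cursor:
                pieces.append((cursor, iv.start, "unannotated"))
            pieces.append((iv.start, iv.end, label))
            cursor = iv.end
        if cursor < stop:
            pieces.append((cursor, stop, "unannotated"))
        tiling[chrom] = pieces

    peak_bp: dict[str, int] = {}
    genome_bp: dict[str, int] = {}
    for chrom, pieces in tiling.items():
        for s, e, label in pieces:
            genome_bp[label] = genome_bp.get(label, 0) + (e - s)
    for iv in merged:
        for s, e, label in tiling.get(iv.chrom, ()):
            ov = max(0, min(e, iv.end) - max(s, iv.start))
            if ov:
                peak_bp[label] = peak_bp.get(label, 0) + ov

    def normalise(d: dict[str, int]) -> dict[str, float]:
        total = sum(d.values())
        return {k: v / total for k, v in d.items()} if total else {}

    return normalise(peak_bp), normalise(genome_bp)
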