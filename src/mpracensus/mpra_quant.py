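"""From raw reads to normalised per-sequence reporter activity.

The pipeline stages mirror barcode-based MPRA processing:

1. **demultiplex** -- the first 35 nt of each read (10-nt barcode + 25-nt
   constant vector flank) are matched against the design's reference
   35-mers allowing one mismatch; reads matching no reference or more than
   one are counted as unassigned / ambiguous;
2. **UMI deduplication** -- reads sharing a barcode are collapsed to
   molecules by the directional-adjacency rule: UMI ``u`` absorbs UMI ``v``
   when Hamming(u, v) <= 1 and count(u) >= 2*count(v) - 1;
3. **filtering** -- a barcode is kept when it has >= 5 molecules in every
   DNA input replicate and, in at least one treatment condition, >= 5
   molecules in every RNA replicate of that condition;
4. **normalisation** -- counts per million within each library, RNA then
   divided by the barcode's mean DNA CPM, then by the median of scramble-
   control values within each RNA library (so scramble activity is 1 by
   construction);
5. **aggregation** -- surviving barcodes of the same (query, allele) are
   averaged into the per-sequence activity table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mpra_design import BARCODE_LENGTH, CONSTANT_FLANK, BarcodePool, DesignManifest

__all__ = [
    "SampleInfo",
    "DemuxResult",
    "BarcodeActivity",
    "ActivityTable",
    "QuantError",
    "NormalizationError",
    "demux_reads",
    "dedup_umis",
    "dedup_counts",
    "raw_counts",
    "filter_barcodes",
    "cpm_normalize",
    "activity_pipeline",
    "compute_activity",
    "aggregate_sequences",
]

READ_UNIT_LENGTH = BARCODE_LENGTH + len(CONSTANT_FLANK)  # 35


class QuantError(ValueError):
    pass


class NormalizationError(QuantError):
    pass


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    library_type: str  # "DNA" | "RNA"
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.library_type not in ("DNA", "RNA"):
            raise QuantError(f"library_type must be DNA or RNA")
        if self.replicate < 1:
            raise QuantError("replicate must be >= 1")


def _dna_ids(samples: Sequence[SampleInfo]) -> list[str]:
    return [s.sample_id for s in samples if s.library_type == "DNA"]


def _rna_ids(samples: Sequence[SampleInfo]) -> list[str]:
    return [s.sample_id for s in samples if s.library_type == "RNA"]


@dataclass
class DemuxResult:
    """Per-sample barcode x UMI read counts plus assignment metrics."""

    counts: dict[str, dict[str, Counter]]  # sample -> barcode -> UMI -> reads
    metrics: pd.DataFrame  # sample, total, assigned, unassigned, ambiguous


def _single_mutants(seq: str) -> Iterable[str]:
    for i in range(len(seq)):
        for b in "ACGT":
            if b != seq[i]:
                yield seq[:i] + b + seq[i + 1 :]


def demux_reads(
    reads_by_sample: Mapping[str, Iterable[tuple[str, str]]],
    pool: BarcodePool | Sequence[str],
    constant_flank: str = CONSTANT_FLANK,
) -> DemuxResult:
    """Assign reads to barcodes with a one-mismatch budget over the 35-mer.

    ``reads_by_sample`` maps sample id to (read sequence, UMI) pairs.  A
    read is assigned when exactly one reference 35-mer (barcode + constant
    flank) lies within Hamming distance 1 of its first 35 bases; mismatches
    in the constant part consume the same budget.  Reads shorter than 35 nt
    are unassigned.
    """
    if len(constant_flank) != READ_UNIT_LENGTH - BARCODE_LENGTH:
        raise QuantError(
            f"constant flank must be {READ_UNIT_LENGTH - BARCODE_LENGTH} nt"
        )
    barcodes = pool.barcodes if isinstance(pool, BarcodePool) else tuple(pool)
    exact: dict[str, str | None] = {}
    near: dict[str, str | None] = {}
    for bc in barcodes:
        if bc in exact:
            exact[bc] = None  # duplicate barcode: inherently ambiguous
        else:
            exact[bc] = bc
        for variant in (bc, *_single_mutants(bc)):
            if variant in near and near[variant] != bc:
                near[variant] = None
            else:
                near[variant] = bc

    counts: dict[str, dict[str, Counter]] = {}
    rows = []
    for sample, reads in reads_by_sample.items():
        per_bc: dict[str, Counter] = {}
        total = assigned = unassigned = ambiguous = 0
        for seq, umi in reads:
            total += 1
            if len(seq) < READ_UNIT_LENGTH:
                unassigned += 1
                continue
            const_mm = 0
            for a, b in zip(seq[BARCODE_LENGTH:READ_UNIT_LENGTH], constant_flank):
                if a != b:
                    const_mm += 1
                    if const_mm > 1:
                        break
            if const_mm > 1:
                unassigned += 1
                continue
            head = seq[:BARCODE_LENGTH]
            if const_mm == 1:
                bc = exact.get(head)
            else:
                bc = near.get(head)
            if bc is None:
                if (const_mm == 1 and head in exact) or (
                    const_mm == 0 and head in near
                ):
                    ambiguous += 1
                else:
                    unassigned += 1
                continue
            per_bc.setdefault(bc, Counter())[umi] += 1
            assigned += 1
        counts[sample] = per_bc
        rows.append(
            {
                "sample": sample,
                "total": total,
                "assigned": assigned,
                "unassigned": unassigned,
                "ambiguous": ambiguous,
            }
        )
    metrics = pd.DataFrame(
        rows, columns=["sample", "total", "assigned", "unassigned", "ambiguous"]
    )
    return DemuxResult(counts=counts, metrics=metrics)


def dedup_umis(umi_counts: Mapping[str, int]) -> int:
    """Molecule count under directional-adjacency UMI collapse.

    Clusters grow from high-count UMIs: an edge u -> v exists when
    Hamming(u, v) <= 1 and count(u) >= 2*count(v) - 1; the number of
    connected clusters reachable by such directed growth is the molecule
    count.
    """
    if not umi_counts:
        return 0
    counts = dict(umi_counts)
    order = sorted(counts, key=lambda u: (-counts[u], u))
    unvisited = set(order)
    clusters = 0
    for root in order:
        if root not in unvisited:
            continue
        clusters += 1
        stack = [root]
        unvisited.discard(root)
        while stack:
            u = stack.pop()
            cu = counts[u]
            for v in _single_mutants(u):
                if v in unvisited and cu >= 2 * counts[v] - 1:
                    unvisited.discard(v)
                    stack.append(v)
    return clusters


def raw_counts(demux: DemuxResult) -> pd.DataFrame:
    """Barcode x sample read counts before deduplication."""
    data = {
        sample: {bc: sum(umis.values()) for bc, umis in per_bc.items()}
        for sample, per_bc in demux.counts.items()
    }
    frame = pd.DataFrame(data).fillna(0).astype(int)
    frame.index.name = "barcode"
    return frame.sort_index()


def dedup_counts(demux: DemuxResult) -> pd.DataFrame:
    """Barcode x sample molecule counts after directional UMI collapse."""
    data = {
        sample: {bc: dedup_umis(umis) for bc, umis in per_bc.items()}
        for sample, per_bc in demux.counts.items()
    }
    frame = pd.DataFrame(data).fillna(0).astype(int)
    frame.index.name = "barcode"
    return frame.sort_index()


def filter_barcodes(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    min_count: int = 5,
) -> pd.DataFrame:
    """Keep barcodes quantified in every DNA replicate and one full condition.

    A barcode survives iff count >= ``min_count`` in all DNA samples AND
    there is at least one condition in which count >= ``min_count`` in
    every RNA replicate of that condition.
    """
    dna = _dna_ids(samples)
    if not dna:
        raise QuantError("no DNA samples in the sample sheet")
    conditions: dict[str, list[str]] = {}
    for s in samples:
        if s.library_type == "RNA":
            conditions.setdefault(s.condition, []).append(s.sample_id)
    if not conditions:
        raise QuantError("no RNA samples in the sample sheet")
    keep = (counts[dna] >= min_count).all(axis=1)
    any_condition = pd.Series(False, index=counts.index)
    for cols in conditions.values():
        any_condition |= (counts[cols] >= min_count).all(axis=1)
    return counts.loc[keep & any_condition]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample column."""
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise QuantError(
            f"zero total count in sample(s): {', '.join(map(str, zero.index))}"
        )
    return counts * 1e6 / sums


@dataclass
class BarcodeActivity:
    """DNA- and scramble-normalised activity per barcode and RNA sample."""

    activity: pd.DataFrame  # barcode x RNA sample
    excluded: tuple[str, ...]  # barcodes dropped for zero DNA abundance
    scramble_median: pd.Series  # per RNA sample


def compute_activity(
    cpm: pd.DataFrame,
    samples: Sequence[SampleInfo],
    manifest: DesignManifest,
    scramble_role: str = "scramble",
    allow_unscaled: bool = False,
) -> BarcodeActivity:
    """RNA CPM over mean DNA CPM, scaled to the scramble median per sample.

    Barcodes with zero mean DNA CPM are excluded (reported in the result).
    Without surviving scramble barcodes a :class:`NormalizationError` is
    raised unless ``allow_unscaled`` requests the raw-ratio fallback.
    """
    dna = _dna_ids(samples)
    rna = _rna_ids(samples)
    if not dna or not rna:
        raise QuantError("need both DNA and RNA samples")
    dna_mean = cpm[dna].mean(axis=1)
    excluded = tuple(dna_mean.index[dna_mean == 0])
    kept = dna_mean.index[dna_mean > 0]
    ratio = cpm.loc[kept, rna].div(dna_mean.loc[kept], axis=0)

    roles = manifest.frame.set_index("barcode")["role"]
    scramble_bcs = [
        bc for bc in kept if roles.get(bc, "") == scramble_role
    ]
    if scramble_bcs:
        med = ratio.loc[scramble_bcs].median(axis=0)
    elif allow_unscaled:
        med = pd.Series(1.0, index=rna)
    else:
        raise NormalizationError(
            "no surviving scramble-control barcodes; pass allow_unscaled=True "
            "for raw RNA/DNA ratios"
        )
    if (med == 0).any():
        raise NormalizationError("scramble median is zero in some RNA sample")
    return BarcodeActivity(
        activity=ratio.div(med, axis=1),
        excluded=excluded,
        scramble_median=med,
    )


@dataclass
class ActivityTable:
    """Mean activity per designed sequence, with surviving barcode counts."""

    activity: pd.DataFrame  # (query_id, allele) x RNA sample
    n_barcodes: pd.Series  # per (query_id, allele)

    def to_tsv(self, path) -> None:
        out = self.activity.copy()
        out["n_barcodes"] = self.n_barcodes
        out.to_csv(path, sep="\t")


def activity_pipeline(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    manifest: DesignManifest,
    min_count: int = 5,
    allow_unscaled: bool = False,
) -> tuple[BarcodeActivity, "ActivityTable"]:
    """Filter -> CPM -> DNA/scramble normalisation -> per-sequence table."""
    filtered = filter_barcodes(counts, samples, min_count=min_count)
    cpm = cpm_normalize(filtered)
    barcode_activity = compute_activity(
        cpm, samples, manifest, allow_unscaled=allow_unscaled
    )
    return barcode_activity, aggregate_sequences(barcode_activity, manifest)


def aggregate_sequences(
    barcode_activity: BarcodeActivity | pd.DataFrame,
    manifest: DesignManifest,
) -> ActivityTable:
    """Average surviving barcodes of each (query_id, allele)."""
    act = (
        barcode_activity.activity
        if isinstance(barcode_activity, BarcodeActivity)
        else barcode_activity
    )
    key = manifest.frame.set_index("barcode")[["query_id", "allele"]]
    joined = act.join(key, how="inner")
    if joined.empty:
        raise QuantError("no surviving barcode maps to the design manifest")
    grouped = joined.groupby(["query_id", "allele"], sort=False)
    mean = grouped[act.columns.tolist()].mean()
    n = grouped.size()
    n.name = "n_barcodes"
    return ActivityTable(activity=mean, n_barcodes=n)
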