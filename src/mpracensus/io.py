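"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; BED is 0-based half-open; VCF output is
v4.2 with 1-based positions; variants, motifs, design manifests, sample
sheets and merged-peak tables are TSV.  FASTQ reads carry their UMI in the
description as ``UMI:<seq>``.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .interval_ops import GeneModel, GenomicInterval, MergedPeak, Peak
from .motif_scan import ConsensusMotif, Variant
from .mpra_quant import SampleInfo

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_bed",
    "read_bed",
    "write_vcf",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_motifs",
    "read_motifs",
    "write_merged_peaks_tsv",
    "read_gtf_genes",
    "write_sample_sheet",
    "read_sample_sheet",
]


def write_fasta(records: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path, prefix: str = "read") -> None:
    """Write (sequence, UMI) pairs; the UMI rides in the description."""

    def records():
        for i, (seq, umi) in enumerate(reads):
            rec = SeqRecord(Seq(seq), id=f"{prefix}{i}", description=f"UMI:{umi}")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    SeqIO.write(records(), str(path), "fastq")


_UMI_RE = re.compile(r"UMI:([ACGTN]+)")


def read_fastq(path) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        m = _UMI_RE.search(rec.description)
        if not m:
            raise ValueError(f"read {rec.id} lacks a UMI:<seq> tag")
        out.append((str(rec.seq), m.group(1)))
    return out


def write_bed(peaks: Sequence[Peak | GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval if isinstance(p, Peak) else p
            if isinstance(p, Peak):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.source or '.'}\t"
                    f"{p.score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_vcf(variants: Sequence[Variant], path, source: str = "mpracensus") -> None:
    """Minimal VCF v4.2 with 1-based positions."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
            )


_VARIANT_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "flank5", "flank3"]


def write_variants_tsv(variants: Sequence[Variant], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "flank5": v.flank5,
                "flank3": v.flank3,
            }
            for v in variants
        ],
        columns=_VARIANT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[Variant]:
    frame = pd.read_csv(path, sep="\t", dtype={"pos": int})
    return [
        Variant(
            rsid=str(r.rsid),
            ref=str(r.ref),
            alt=str(r.alt),
            flank5=str(r.flank5),
            flank3=str(r.flank3),
            chrom=str(r.chrom),
            pos=int(r.pos),
        )
        for r in frame.itertuples(index=False)
    ]


def write_motifs(motifs: Sequence[ConsensusMotif], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\n")


def read_motifs(path) -> list[ConsensusMotif]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pattern = line.split("\t")
            out.append(ConsensusMotif(name, pattern))
    return out


def write_merged_peaks_tsv(merged: Sequence[MergedPeak], path) -> None:
    """Merged regions with one boolean column per contributing source."""
    labels = sorted({lab for m in merged for lab in m.members})
    rows = []
    for m in merged:
        row = {"chrom": m.interval.chrom, "start": m.interval.start,
               "end": m.interval.end}
        for lab in labels:
            row[lab] = bool(m.members.get(lab, False))
        rows.append(row)
    pd.DataFrame(rows, columns=["chrom", "start", "end", *labels]).to_csv(
        path, sep="\t", index=False
    )


_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path) -> list[GeneModel]:
    """Minimal GTF-subset reader: gene/transcript/exon lines only.

    One :class:`GeneModel` per transcript; the TSS is the strand-aware
    transcript start.  Transcripts without exon lines get the transcript
    span as a single exon.
    """
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("transcript", "exon", "gene"):
                continue
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id") or attr.get("gene_id")
            if tid is None:
                continue
            entry = transcripts.setdefault(
                tid,
                {
                    "gene_id": attr.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "span": None,
                    "exons": [],
                },
            )
            s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feature == "exon":
                entry["exons"].append((s, e))
            else:
                entry["span"] = (s, e)
    genes = []
    for entry in transcripts.values():
        exons = entry["exons"] or ([entry["span"]] if entry["span"] else [])
        if not exons:
            continue
        lo = min(s for s, _ in exons)
        hi = max(e for _, e in exons)
        tss = lo if entry["strand"] == "+" else hi - 1
        genes.append(
            GeneModel(
                gene_id=entry["gene_id"],
                chrom=entry["chrom"],
                tss=tss,
                strand=entry["strand"],
                exons=tuple(sorted(exons)),
            )
        )
    return genes


def write_sample_sheet(samples: Sequence[SampleInfo], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "library_type": s.library_type,
                "condition": s.condition,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[SampleInfo]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        SampleInfo(
            sample_id=str(r.sample_id),
            library_type=str(r.library_type),
            condition=str(r.condition),
            replicate=int(r.replicate),
        )
        for r in frame.itertuples(index=False)
    ]
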