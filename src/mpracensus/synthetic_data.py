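"""Synthetic reporter-assay studies with known ground truth.

Generates every input the census/MPRA pipeline consumes: a reference
sequence with bZIP composite motifs planted inside declared peak regions,
biallelic SNPs placed at chosen positions within (or outside) those motifs,
a barcoded library design with scramble controls, and DNA-input / RNA
barcode count matrices (optionally expanded into reads carrying UMIs,
sequencing errors and PCR duplicates).

The default configuration mirrors the reference study design: two
conditions (control and tunicamycin-style stress), five RNA replicates per
condition, three DNA input replicates, six barcodes per candidate allele,
three per control, a ~20% scramble-control subset, and a mean depth of 500
reads per barcode.  Counts follow a negative binomial with dispersion 0.1;
allelic effects enter the RNA mean as +/- half the variant's log2 fold
change per allele, treatment effects as a per-sequence log2 shift in the
stressed condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .interval_ops import GenomicInterval, Peak
from .motif_scan import (
    BASES,
    DEFAULT_MOTIFS,
    ConsensusMotif,
    Variant,
    reverse_complement,
    variant_motif_hits,
)
from .mpra_design import (
    CONSTANT_FLANK,
    DESIGN_FLANK_DEFAULT,
    DesignManifest,
    OligoRecord,
    assemble_oligo,
    assign_barcodes,
    dinucleotide_shuffle,
    generate_barcode_pool,
    sanitize_query,
)
from .mpra_quant import SampleInfo

__all__ = [
    "SimConfig",
    "SimError",
    "PlantedMotif",
    "ReferencePanel",
    "SimDesign",
    "SimTruth",
    "make_reference_panel",
    "build_design",
    "build_truth",
    "simulate_counts",
    "simulate_reads",
    "SimReads",
    "simulate_study",
]

DESIGN_FLANK = DESIGN_FLANK_DEFAULT  # 87 nt per side of the centred SNP
READ_FILLER = "GTGCCTAAAGGACTG"
UMI_LENGTH = 12
_SLOT_SPACING = 250
_SLOT_MARGIN = 150

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic reporter experiment."""

    seed: int = 0
    n_variants: int = 50
    motif_offset_distribution: Mapping[int, float] | None = None
    fraction_outside_motif: float = 0.2
    reference_length: int | None = None
    n_replicates_per_condition: int = 5
    n_dna_replicates: int = 3
    conditions: tuple[str, str] = ("ctrl", "tun")
    mean_dna_depth: float = 500.0
    mean_rna_depth: float = 500.0
    pcr_duplication_rate: float = 0.1
    seq_error_rate: float = 0.001
    allelic_log2fc_sd: float = 0.5
    treatment_log2fc_mean: float = 1.0
    treatment_log2fc_sd: float = 0.25
    nb_dispersion: float = 0.1
    scramble_fraction: float = 0.2
    barcodes_per_allele: int = 6
    barcodes_per_control: int = 3

    def __post_init__(self) -> None:
        for name in (
            "fraction_outside_motif",
            "pcr_duplication_rate",
            "seq_error_rate",
            "scramble_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_dna_depth <= 0 or self.mean_rna_depth <= 0:
            raise SimError("depths must be positive")
        if self.n_variants < 1:
            raise SimError("need at least one variant")
        if self.motif_offset_distribution is not None:
            d = self.motif_offset_distribution
            if not set(d) <= set(range(1, 11)):
                raise SimError("motif offsets must lie in 1..10")
            total = float(sum(d.values()))
            if not np.isclose(total, 1.0):
                raise SimError("offset probabilities must sum to 1")

    def offset_probabilities(self) -> np.ndarray:
        probs = np.zeros(10)
        if self.motif_offset_distribution is None:
            probs[:] = 0.1
        else:
            for off, p in self.motif_offset_distribution.items():
                probs[off - 1] = p
        return probs

    def rng_for(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def derived_seed(self, stream: int) -> int:
        return int(
            np.random.SeedSequence([int(self.seed), int(stream)]).generate_state(1)[0]
            % (2**31)
        )


@dataclass(frozen=True)
class PlantedMotif:
    name: str
    strand: str
    offset: int  # variant position within the 10-mer, pattern orientation
    motif_start: int  # genome coordinate of the planted 10-mer (0-based)
    realized_10mer: str  # pattern orientation, intact allele


@dataclass
class ReferencePanel:
    chrom: str
    reference: str
    peaks: list[Peak]
    variants: list[Variant]
    planted: dict[str, PlantedMotif | None]
    intact_allele: dict[str, str]  # ref | alt | both | neither


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASE_BYTES[rng.integers(0, 4, size=n)]


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def make_reference_panel(
    config: SimConfig, motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS
) -> ReferencePanel:
    """Reference sequence with planted motifs, peaks and a variant panel.

    Each variant occupies its own slot; in-motif variants sit at a sampled
    position (1..10, pattern orientation) of a planted motif whose strand
    and identity are drawn uniformly; which allele keeps the motif intact
    is randomised.  The remaining fraction of variants is verified to match
    no motif with either allele.  All variants carry 87-nt true flanks.
    """
    rng = config.rng_for(1)
    n = config.n_variants
    positions = [_SLOT_MARGIN + _SLOT_SPACING * i for i in range(n)]
    required = positions[-1] + _SLOT_MARGIN
    length = config.reference_length or required
    if length < required:
        raise SimError(
            f"reference_length {length} too short for {n} variants "
            f"(need >= {required})"
        )
    ref_arr = _random_seq(rng, length)

    n_outside = int(round(config.fraction_outside_motif * n))
    outside = set(rng.choice(n, size=n_outside, replace=False).tolist())
    offset_probs = config.offset_probabilities()

    variants: list[Variant] = []
    planted: dict[str, PlantedMotif | None] = {}
    intact_map: dict[str, str] = {}
    peaks: list[Peak] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    for i, p in enumerate(positions):
        rsid = f"snp{i:04d}"
        peaks.append(
            Peak(
                interval=GenomicInterval("chrS", p - 150, p + 150),
                summit=p,
                score=float(rng.uniform(10, 100)),
                source="sim",
            )
        )
        if i in outside:
            for _ in range(200):
                local = _random_seq(rng, 19)
                ref_arr[p - 9 : p + 10] = local
                ref_base = chr(ref_arr[p])
                alt_base = str(rng.choice([b for b in BASES if b != ref_base]))
                v = Variant(
                    rsid=rsid,
                    ref=ref_base,
                    alt=alt_base,
                    flank5=_decode(ref_arr[p - DESIGN_FLANK : p]),
                    flank3=_decode(ref_arr[p + 1 : p + 1 + DESIGN_FLANK]),
                    chrom="chrS",
                    pos=p + 1,
                )
                if not variant_motif_hits(v, motifs):
                    break
            else:
                raise SimError(f"could not place motif-free variant {rsid}")
            planted[rsid] = None
            intact_map[rsid] = "neither"
            variants.append(v)
            continue

        motif = motifs[int(rng.integers(0, len(motifs)))]
        offset = int(rng.choice(np.arange(1, 11), p=offset_probs))
        strand = "+" if rng.random() < 0.5 else "-"
        is_n_position = motif.pattern[offset - 1] == "N"
        intact = "both" if is_n_position else ("ref" if rng.random() < 0.5 else "alt")

        for _ in range(200):
            realized = "".join(
                b if b != "N" else str(rng.choice(list(BASES)))
                for b in motif.pattern
            )
            segment = realized if strand == "+" else reverse_complement(realized)
            start = p - (offset - 1) if strand == "+" else p - (10 - offset)
            ref_arr[start : start + 10] = np.frombuffer(
                segment.encode(), dtype=np.uint8
            )
            motif_base = realized[offset - 1]
            genome_base = motif_base if strand == "+" else comp[motif_base]
            other = str(rng.choice([b for b in BASES if b != genome_base]))
            if intact == "alt":
                ref_arr[p] = ord(other)
                ref_allele, alt_allele = other, genome_base
            else:
                ref_arr[p] = ord(genome_base)
                ref_allele, alt_allele = genome_base, other
            v = Variant(
                rsid=rsid,
                ref=ref_allele,
                alt=alt_allele,
                flank5=_decode(ref_arr[p - DESIGN_FLANK : p]),
                flank3=_decode(ref_arr[p + 1 : p + 1 + DESIGN_FLANK]),
                chrom="chrS",
                pos=p + 1,
            )
            hits = variant_motif_hits(v, motifs)
            if is_n_position:
                ok = any(
                    h.allele == "ref" and h.motif == motif.name for h in hits
                ) and any(
                    h.allele == "alt" and h.motif == motif.name for h in hits
                )
            else:
                intact_hits = [h for h in hits if h.allele == intact]
                broken_hits = [h for h in hits if h.allele != intact]
                ok = bool(intact_hits) and not broken_hits
            if ok:
                break
        else:
            raise SimError(f"could not realise planted motif for {rsid}")
        planted[rsid] = PlantedMotif(
            name=motif.name,
            strand=strand,
            offset=offset,
            motif_start=start,
            realized_10mer=realized,
        )
        intact_map[rsid] = intact
        variants.append(v)

    return ReferencePanel(
        chrom="chrS",
        reference=_decode(ref_arr),
        peaks=peaks,
        variants=variants,
        planted=planted,
        intact_allele=intact_map,
    )


@dataclass
class SimDesign:
    manifest: DesignManifest
    query_seqs: dict[tuple[str, str], str]
    oligos: list[OligoRecord]
    scramble_of: dict[str, str]  # scramble query_id -> source rsid


def build_design(
    panel: ReferencePanel,
    config: SimConfig,
    build_oligos: bool = True,
    barcode_mode: str = "pool",
) -> SimDesign:
    """Design the reporter library for a synthetic panel.

    175-nt queries centred on each variant (both alleles), sanitised of
    cloning restriction sites; a random ``scramble_fraction`` subset of
    regions contributes a dinucleotide-preserving shuffled scramble
    control; barcodes come from a freshly generated distance-3 pool
    (``barcode_mode="pool"``).  ``barcode_mode="enumerated"`` instead uses
    deterministic distinct 10-mers with no filter or distance guarantee --
    suitable only for count-level studies that never demultiplex reads.
    """
    rng = config.rng_for(2)
    ref = panel.reference
    queries: list[tuple[str, str, str]] = []
    seqs: dict[tuple[str, str], str] = {}
    edit_logs: dict[tuple[str, str], tuple] = {}

    for v in panel.variants:
        p = v.pos - 1
        base_query = ref[p - DESIGN_FLANK : p + 1 + DESIGN_FLANK]
        for which, allele in (("ref", v.ref), ("alt", v.alt)):
            raw = base_query[:DESIGN_FLANK] + allele + base_query[DESIGN_FLANK + 1 :]
            clean, edits = sanitize_query(raw, DESIGN_FLANK)
            queries.append((v.rsid, which, "candidate"))
            seqs[(v.rsid, which)] = clean
            edit_logs[(v.rsid, which)] = tuple(edits)

    n_scramble = int(round(config.scramble_fraction * len(panel.variants)))
    scramble_of: dict[str, str] = {}
    if n_scramble:
        chosen = rng.choice(len(panel.variants), size=n_scramble, replace=False)
        for idx in sorted(chosen.tolist()):
            v = panel.variants[idx]
            qid = f"{v.rsid}_scr"
            shuffled = dinucleotide_shuffle(seqs[(v.rsid, "ref")], rng)
            clean, edits = sanitize_query(shuffled, DESIGN_FLANK)
            queries.append((qid, "scr", "scramble"))
            seqs[(qid, "scr")] = clean
            edit_logs[(qid, "scr")] = tuple(edits)
            scramble_of[qid] = v.rsid

    demand = (
        2 * config.barcodes_per_allele * len(panel.variants)
        + config.barcodes_per_control * n_scramble
    )
    if barcode_mode == "pool":
        pool = generate_barcode_pool(demand, seed=config.derived_seed(10))
    elif barcode_mode == "enumerated":
        pool = _enumerated_barcodes(demand)
    else:
        raise SimError(f"unknown barcode_mode {barcode_mode!r}")
    manifest = assign_barcodes(
        queries,
        pool,
        seed=config.derived_seed(11),
        barcodes_per_role={
            "candidate": config.barcodes_per_allele,
            "scramble": config.barcodes_per_control,
        },
    )
    oligos: list[OligoRecord] = []
    if build_oligos:
        for row in manifest.frame.itertuples(index=False):
            key = (row.query_id, row.allele)
            oligos.append(
                assemble_oligo(
                    row.query_id,
                    row.allele,
                    seqs[key],
                    row.barcode,
                    edits=edit_logs[key],
                )
            )
    return SimDesign(
        manifest=manifest, query_seqs=seqs, oligos=oligos, scramble_of=scramble_of
    )


def _enumerated_barcodes(n: int):
    """Distinct 10-mers by base-4 index encoding (no pool guarantees)."""
    from .mpra_design import BARCODE_LENGTH, BarcodePool

    if n > 4**BARCODE_LENGTH:
        raise SimError("barcode space exhausted")
    seqs = []
    for i in range(n):
        digits = []
        x = i
        for _ in range(BARCODE_LENGTH):
            digits.append(BASES[x % 4])
            x //= 4
        seqs.append("".join(digits))
    return BarcodePool(barcodes=tuple(seqs), seed=-1)


@dataclass
class SimTruth:
    """Ground truth planted into a simulated study."""

    allelic_log2fc: dict[str, float]  # per variant, ref over alt
    treatment_log2fc: dict[tuple[str, str], float]  # per (query_id, allele)
    barcode_abundance: dict[str, float]  # relative plasmid-pool abundance
    planted: dict[str, PlantedMotif | None]


def build_truth(
    panel: ReferencePanel, design: SimDesign, config: SimConfig
) -> SimTruth:
    """Draw per-variant allelic and per-sequence treatment effects.

    Allelic log2 fold changes ~ N(0, allelic_log2fc_sd); candidate
    treatment effects ~ N(treatment_log2fc_mean, treatment_log2fc_sd);
    scramble controls are treatment-inert; barcode abundances are
    lognormal.  Override fields on the returned object to plant specific
    effects.
    """
    rng = config.rng_for(3)
    allelic = {
        v.rsid: float(rng.normal(0.0, config.allelic_log2fc_sd))
        for v in panel.variants
    }
    treatment: dict[tuple[str, str], float] = {}
    for qid, allele, role in (
        design.manifest.frame[["query_id", "allele", "role"]]
        .drop_duplicates()
        .itertuples(index=False)
    ):
        if role == "candidate":
            treatment[(qid, allele)] = float(
                rng.normal(config.treatment_log2fc_mean, config.treatment_log2fc_sd)
            )
        else:
            treatment[(qid, allele)] = 0.0
    abundance = {
        bc: float(rng.lognormal(mean=0.0, sigma=0.5))
        for bc in design.manifest.barcodes
    }
    return SimTruth(
        allelic_log2fc=allelic,
        treatment_log2fc=treatment,
        barcode_abundance=abundance,
        planted=dict(panel.planted),
    )


def _sample_sheet(config: SimConfig) -> list[SampleInfo]:
    samples = [
        SampleInfo(f"dna_{r}", "DNA", "", r)
        for r in range(1, config.n_dna_replicates + 1)
    ]
    for cond in config.conditions:
        for r in range(1, config.n_replicates_per_condition + 1):
            samples.append(SampleInfo(f"rna_{cond}_{r}", "RNA", cond, r))
    return samples


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def simulate_counts(
    design: SimDesign | DesignManifest,
    truth: SimTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, list[SampleInfo]]:
    """Molecule counts per barcode and library.

    DNA counts are negative binomial around depth x barcode abundance; RNA
    counts around the same share multiplied by 2 to the power of (allele
    sign x allelic effect / 2 + treatment effect x treated indicator).
    Treated samples are all conditions after the first.
    """
    manifest = design.manifest if isinstance(design, SimDesign) else design
    missing = [bc for bc in manifest.barcodes if bc not in truth.barcode_abundance]
    if missing:
        raise SimError(f"{len(missing)} design barcodes absent from truth")
    rng = config.rng_for(4)
    samples = _sample_sheet(config)
    frame = manifest.frame
    abund = np.array([truth.barcode_abundance[b] for b in frame["barcode"]])

    shift = np.zeros(len(frame))
    treat = np.zeros(len(frame))
    for i, row in enumerate(frame.itertuples(index=False)):
        if row.role == "candidate":
            lfc = truth.allelic_log2fc.get(row.query_id, 0.0)
            shift[i] = 0.5 * lfc if row.allele == "ref" else -0.5 * lfc
        treat[i] = truth.treatment_log2fc.get((row.query_id, row.allele), 0.0)

    data = {}
    baseline = config.conditions[0]
    for s in samples:
        if s.library_type == "DNA":
            mu = config.mean_dna_depth * abund
        else:
            treated = s.condition != baseline
            mu = (
                config.mean_rna_depth
                * abund
                * np.exp2(shift + (treat if treated else 0.0))
            )
        data[s.sample_id] = _nb_draw(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(data, index=pd.Index(frame["barcode"], name="barcode"))
    return counts, samples


def _decode_rows(arr: np.ndarray) -> list[str]:
    return [row.tobytes().decode() for row in arr]


@dataclass
class SimReads:
    """Simulated read sets plus the molecule ledger behind them.

    ``umi_ledger`` records, per sample and barcode, the true UMIs drawn for
    each molecule (before PCR duplication and sequencing error).  Distinct
    molecules can by chance draw UMIs within Hamming distance 1 of each
    other; directional deduplication merges such pairs, so the exact
    molecule count recoverable by the pipeline is the directional collapse
    of this ledger rather than the raw molecule count.
    """

    reads: dict[str, list[tuple[str, str]]]
    umi_ledger: dict[str, dict[str, list[str]]]


def simulate_reads(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    config: SimConfig,
) -> SimReads:
    """Expand molecule counts into (read sequence, UMI) records per sample.

    Each molecule yields a read of barcode + 25-nt constant flank + vector
    filler and a random 12-nt UMI; PCR duplicates re-emit the molecule with
    the same UMI (fresh sequencing errors), substitution errors hit every
    base independently at ``seq_error_rate``.
    """
    rng = config.rng_for(5)
    dup = config.pcr_duplication_rate
    err = config.seq_error_rate
    reads: dict[str, list[tuple[str, str]]] = {}
    ledger: dict[str, dict[str, list[str]]] = {}
    for s in samples:
        out: list[tuple[str, str]] = []
        led: dict[str, list[str]] = {}
        col = counts[s.sample_id]
        for bc, m in col.items():
            m = int(m)
            if m == 0:
                continue
            base_read = bc + CONSTANT_FLANK + READ_FILLER
            umis = _decode_rows(_BASE_BYTES[rng.integers(0, 4, size=(m, UMI_LENGTH))])
            led[bc] = umis
            copies = rng.geometric(1.0 - dup, size=m) if dup > 0 else np.ones(m, int)
            for umi, k in zip(umis, copies):
                for _ in range(int(k)):
                    out.append(
                        (_inject_errors(base_read, err, rng),
                         _inject_errors(umi, err, rng))
                    )
        reads[s.sample_id] = out
        ledger[s.sample_id] = led
    return SimReads(reads=reads, umi_ledger=ledger)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        arr[pos] = str(rng.choice([b for b in BASES if b != arr[pos]]))
    return "".join(arr)


@dataclass
class SimStudy:
    config: SimConfig
    panel: ReferencePanel
    design: SimDesign
    truth: SimTruth
    counts: pd.DataFrame
    samples: list[SampleInfo]


def simulate_study(config: SimConfig, build_oligos: bool = False) -> SimStudy:
    """End-to-end convenience: panel -> design -> truth -> counts."""
    panel = make_reference_panel(config)
    design = build_design(panel, config, build_oligos=build_oligos)
    truth = build_truth(panel, design, config)
    counts, samples = simulate_counts(design, truth, config)
    return SimStudy(
        config=config,
        panel=panel,
        design=design,
        truth=truth,
        counts=counts,
        samples=samples,
    )
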