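"""Allele-aware scanning of variants against bZIP composite binding motifs.

ATF4 binds DNA as a homodimer or as heterodimers with other bZIP factors
(C/EBP family, AP-1 family, BATF), recognising a family of closely related
composite elements.  Following the convention of treating the two positions
flanking the core 8-mer as informative "lenient" positions, each motif is
represented as a 10-mer consensus over {A, C, G, T, N}, where N marks a
lenient (unconstrained) position:

====================  ============
motif                 consensus
====================  ============
C/EBP-ATF             NTGATGNAAN
CRE                   NTGACGTCAN
BATF-ATF              NTGACGTGNC
CREB-C/EBP            NTGACGNAAN
====================  ============

A biallelic variant is scanned by embedding each allele in 9 bp of genomic
flank and sliding every 10-bp window that covers the variant base across
both strands.  The per-allele hit lists are then condensed into one of four
motif-alteration categories:

``none``
    neither allele matches any motif;
``lenient_change``
    both alleles match the same motif, the variant falling on an N
    position (the motif survives on both alleles);
``disruption``
    exactly one allele carries a match -- the classic case where the other
    allele breaks a constrained motif position;
``switch``
    the two alleles match disjoint motif sets, e.g. a single substitution
    converting a CREB-C/EBP element into a C/EBP-ATF element.

An optional position-weight-matrix (PWM) route scores the same windows by
log-odds and is used to cross-check the consensus census.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOTIF_LENGTH",
    "ConsensusMotif",
    "DEFAULT_MOTIFS",
    "Variant",
    "MotifHit",
    "VariantMotifCall",
    "Pwm",
    "reverse_complement",
    "consensus_match",
    "allele_context",
    "variant_motif_hits",
    "classify_variant",
    "pwm_from_consensus",
    "pwm_scan",
    "compare_consensus_vs_pwm",
    "scan_panel",
]

MOTIF_LENGTH = 10
FLANK_FOR_SCAN = 9

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")
_VALID_ACGT = re.compile(r"^[ACGT]+$")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


class MotifScanError(ValueError):
    """Raised on malformed sequence input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence over A/C/G/T/N (case kept)."""
    if not _VALID_SEQ.match(seq):
        raise MotifScanError(f"sequence contains non-ACGTN characters: {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusMotif:
    """A 10-mer consensus with N marking lenient positions."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) != MOTIF_LENGTH:
            raise MotifScanError(
                f"motif {self.name!r}: pattern must be {MOTIF_LENGTH} nt, "
                f"got {len(self.pattern)}"
            )
        if not set(self.pattern) <= set("ACGTN"):
            raise MotifScanError(f"motif {self.name!r}: invalid characters")

    def n_positions(self) -> tuple[int, ...]:
        """1-based positions that are lenient (N)."""
        return tuple(i + 1 for i, b in enumerate(self.pattern) if b == "N")


#: The four composite elements reported to bind ATF4-containing bZIP dimers.
DEFAULT_MOTIFS: tuple[ConsensusMotif, ...] = (
    ConsensusMotif("CEBP-ATF", "NTGATGNAAN"),
    ConsensusMotif("CRE", "NTGACGTCAN"),
    ConsensusMotif("BATF-ATF", "NTGACGTGNC"),
    ConsensusMotif("CREB-CEBP", "NTGACGNAAN"),
)


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with flanking genomic sequence.

    ``flank5``/``flank3`` must be at least 9 nt for motif scanning and at
    least 87 nt when the variant is used for reporter-library design.
    """

    rsid: str
    ref: str
    alt: str
    flank5: str
    flank3: str
    chrom: str = "."
    pos: int = 0  # 1-based position of the first ref base

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise MotifScanError(f"{self.rsid}: ref and alt alleles are identical")
        for label, seq in (("ref", self.ref), ("alt", self.alt)):
            if not _VALID_ACGT.match(seq):
                raise MotifScanError(f"{self.rsid}: {label} allele {seq!r} invalid")
        for label, seq in (("flank5", self.flank5), ("flank3", self.flank3)):
            if seq and not _VALID_ACGT.match(seq):
                raise MotifScanError(f"{self.rsid}: {label} is not A/C/G/T only")

    def allele(self, which: str) -> str:
        if which == "ref":
            return self.ref
        if which == "alt":
            return self.alt
        raise MotifScanError(f"unknown allele label {which!r}")


@dataclass(frozen=True)
class MotifHit:
    """One motif window overlapping the variant base on one allele.

    ``offset`` is the window start (0-based) within the scanned allele
    context; ``variant_position_in_motif`` is 1..10 in the orientation of
    the consensus pattern itself, and ``matched_10mer`` is the window read
    in that same orientation.
    """

    rsid: str
    allele: str
    motif: str
    strand: str
    offset: int
    matched_10mer: str
    variant_position_in_motif: int


@dataclass(frozen=True)
class VariantMotifCall:
    """Classification of a variant's effect on the motif repertoire."""

    rsid: str
    category: str  # none | lenient_change | disruption | switch
    intact_allele: str  # ref | alt | both | neither
    motifs_by_allele: Mapping[str, tuple[MotifHit, ...]]


def consensus_match(window: str, motif: ConsensusMotif) -> bool:
    """True iff every non-N consensus position equals the window base."""
    if len(window) != MOTIF_LENGTH:
        raise MotifScanError(
            f"window must be {MOTIF_LENGTH} nt, got {len(window)}: {window!r}"
        )
    if not _VALID_ACGT.match(window):
        raise MotifScanError(f"window is not A/C/G/T only: {window!r}")
    return all(p == "N" or p == b for p, b in zip(motif.pattern, window))


def allele_context(variant: Variant, which: str) -> tuple[str, int]:
    """Allele embedded in 9 bp flanks; returns (sequence, index of first
    allele base within it)."""
    for label, seq in (("flank5", variant.flank5), ("flank3", variant.flank3)):
        if len(seq) < FLANK_FOR_SCAN:
            raise MotifScanError(
                f"{variant.rsid}: {label} shorter than {FLANK_FOR_SCAN} nt"
            )
    left = variant.flank5[-FLANK_FOR_SCAN:]
    right = variant.flank3[:FLANK_FOR_SCAN]
    return left + variant.allele(which) + right, len(left)


def variant_motif_hits(
    variant: Variant, motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS
) -> list[MotifHit]:
    """All motif windows covering the variant base, both alleles and strands.

    Hits are deduplicated by (allele, motif, strand, offset);
    ``variant_position_in_motif`` refers to the first altered base, which for
    an indel is the first base of the allele.
    """
    hits: list[MotifHit] = []
    for which in ("ref", "alt"):
        seq, var_index = allele_context(variant, which)
        lo = max(0, var_index - (MOTIF_LENGTH - 1))
        hi = min(len(seq) - MOTIF_LENGTH, var_index)
        for start in range(lo, hi + 1):
            window = seq[start : start + MOTIF_LENGTH]
            pos_plus = var_index - start + 1
            rc = reverse_complement(window)
            for motif in motifs:
                if consensus_match(window, motif):
                    hits.append(
                        MotifHit(
                            rsid=variant.rsid,
                            allele=which,
                            motif=motif.name,
                            strand="+",
                            offset=start,
                            matched_10mer=window,
                            variant_position_in_motif=pos_plus,
                        )
                    )
                if consensus_match(rc, motif):
                    hits.append(
                        MotifHit(
                            rsid=variant.rsid,
                            allele=which,
                            motif=motif.name,
                            strand="-",
                            offset=start,
                            matched_10mer=rc,
                            variant_position_in_motif=MOTIF_LENGTH + 1 - pos_plus,
                        )
                    )
    return hits


def classify_variant(
    variant: Variant,
    motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS,
    hits: Iterable[MotifHit] | None = None,
) -> VariantMotifCall:
    """Condense per-allele hit lists into a motif-alteration category.

    If both alleles match the same motif name but at no common
    (strand, offset) window, the motif is preserved on both alleles and the
    variant is still reported as ``lenient_change`` (no direction can be
    predicted; see the methods note).
    """
    if hits is None:
        hits = variant_motif_hits(variant, motifs)
    by_allele: dict[str, list[MotifHit]] = {"ref": [], "alt": []}
    for h in hits:
        by_allele[h.allele].append(h)
    ref_hits, alt_hits = by_allele["ref"], by_allele["alt"]

    if not ref_hits and not alt_hits:
        category, intact = "none", "neither"
    elif bool(ref_hits) != bool(alt_hits):
        category = "disruption"
        intact = "ref" if ref_hits else "alt"
    else:
        shared_names = {h.motif for h in ref_hits} & {h.motif for h in alt_hits}
        if not shared_names:
            category, intact = "switch", "both"
        else:
            category, intact = "lenient_change", "both"
    return VariantMotifCall(
        rsid=variant.rsid,
        category=category,
        intact_allele=intact,
        motifs_by_allele={"ref": tuple(ref_hits), "alt": tuple(alt_hits)},
    )


# ---------------------------------------------------------------------------
# PWM route


@dataclass
class Pwm:
    """Position probability matrix with uniform or supplied background.

    ``probabilities`` is a 4 x L matrix in A, C, G, T row order; every
    column must sum to 1.  Scores are sum over positions of
    log2(p_base / background_base), probabilities floored at 1e-3.
    """

    name: str
    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.shape[0] != 4:
            raise MotifScanError("PWM must have 4 rows (A, C, G, T)")
        colsums = self.probabilities.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise MotifScanError("PWM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]

    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.probabilities, 1e-3)
        bg = np.maximum(self.background, 1e-3)[:, None]
        return np.log2(p / bg)


def pwm_from_consensus(
    motif: ConsensusMotif, match_probability: float = 0.997
) -> Pwm:
    """1:1 PWM for a consensus: constrained positions concentrate
    ``match_probability`` on the consensus base, N positions are uniform.

    The threshold is the score of the worst consensus-consistent 10-mer, so
    that at the default threshold the PWM hit set contains the consensus
    hit set.
    """
    probs = np.full((4, MOTIF_LENGTH), 0.25)
    off = (1.0 - match_probability) / 3.0
    for j, b in enumerate(motif.pattern):
        if b != "N":
            probs[:, j] = off
            probs[_BASE_INDEX[b], j] = match_probability
    pwm = Pwm(name=motif.name, probabilities=probs)
    lo = pwm.log_odds()
    # worst consistent window: consensus base at constrained positions,
    # per-column minimum at N positions
    threshold = 0.0
    for j, b in enumerate(motif.pattern):
        threshold += lo[_BASE_INDEX[b], j] if b != "N" else lo[:, j].min()
    pwm.threshold = threshold
    return pwm


def _score_window(window: str, log_odds: np.ndarray) -> float:
    return float(
        sum(log_odds[_BASE_INDEX[b], j] for j, b in enumerate(window))
    )


def pwm_scan(variant: Variant, pwm: Pwm) -> dict[str, tuple[float, bool]]:
    """Best log-odds score per allele over variant-covering windows and
    strands, and whether it reaches the PWM threshold."""
    lo = pwm.log_odds()
    out: dict[str, tuple[float, bool]] = {}
    for which in ("ref", "alt"):
        seq, var_index = allele_context(variant, which)
        best = -np.inf
        first = max(0, var_index - (pwm.length - 1))
        last = min(len(seq) - pwm.length, var_index)
        for start in range(first, last + 1):
            window = seq[start : start + pwm.length]
            best = max(
                best,
                _score_window(window, lo),
                _score_window(reverse_complement(window), lo),
            )
        out[which] = (best, best >= pwm.threshold)
    return out


def compare_consensus_vs_pwm(
    variants: Sequence[Variant],
    motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS,
    pwm: Pwm | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Contingency of consensus vs PWM variant discovery.

    Returns (counts, per-variant table).  ``counts`` has keys ``both``,
    ``consensus_only``, ``pwm_only``, ``neither``, ``either``.  The table
    carries each variant's best PWM score and, for PWM-only variants, the
    percentile of that score among all PWM-found variants.
    """
    if pwm is None:
        pwm = pwm_from_consensus(motifs[0])
    rows = []
    for v in variants:
        cons_hit = bool(variant_motif_hits(v, motifs))
        scores = pwm_scan(v, pwm)
        best = max(s for s, _ in scores.values())
        pwm_hit = any(flag for _, flag in scores.values())
        rows.append(
            {
                "rsid": v.rsid,
                "consensus_hit": cons_hit,
                "pwm_hit": pwm_hit,
                "best_pwm_score": best,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["rsid", "consensus_hit", "pwm_hit", "best_pwm_score"]
    )
    if len(frame):
        found = frame[frame["pwm_hit"]]
        frame["pwm_score_percentile"] = np.nan
        if len(found):
            ranks = found["best_pwm_score"].rank(pct=True) * 100.0
            frame.loc[found.index, "pwm_score_percentile"] = ranks
    else:
        frame["pwm_score_percentile"] = pd.Series(dtype=float)
    counts = {
        "both": int((frame["consensus_hit"] & frame["pwm_hit"]).sum()),
        "consensus_only": int((frame["consensus_hit"] & ~frame["pwm_hit"]).sum()),
        "pwm_only": int((~frame["consensus_hit"] & frame["pwm_hit"]).sum()),
        "neither": int((~frame["consensus_hit"] & ~frame["pwm_hit"]).sum()),
        "either": int((frame["consensus_hit"] | frame["pwm_hit"]).sum()),
    }
    return counts, frame


def scan_panel(
    variants: Sequence[Variant], motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS
) -> pd.DataFrame:
    """One classification row per variant (TSV-ready)."""
    rows = []
    for v in variants:
        call = classify_variant(v, motifs)
        rows.append(
            {
                "rsid": v.rsid,
                "category": call.category,
                "intact_allele": call.intact_allele,
                "ref_motifs": ",".join(
                    sorted({h.motif for h in call.motifs_by_allele["ref"]})
                ),
                "alt_motifs": ",".join(
                    sorted({h.motif for h in call.motifs_by_allele["alt"]})
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["rsid", "category", "intact_allele", "ref_motifs", "alt_motifs"]
    )
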