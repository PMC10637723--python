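"""MPRA library design: barcodes, query sanitisation, oligo assembly.

The reporter construct is a 230-nt single-stranded oligo:

    5'-ACTGGCCGCTTCACTG-(175 nt query)-GGTACCTCTAGA-(10 nt barcode)-AGATCGGAAGAGCGTCG-3'

The query holds the variant at its centre with 87 nt of genomic flank per
side.  Barcodes are drawn from the 10-mer space and filtered so that none
resembles a regulatory or processing signal (homopolymers, extreme GC,
KpnI/XbaI sites, poly-adenylation signal, TF motif matches in vector
context, miRNA target seeds, self-complementarity), then thinned to a
minimum pairwise Hamming distance of 3 -- which guarantees that any read
barcode with at most one sequencing error is within distance 1 of at most
one pool member.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interval_ops import GeneModel
from .motif_scan import (
    BASES,
    DEFAULT_MOTIFS,
    ConsensusMotif,
    Pwm,
    Variant,
    _score_window,
    reverse_complement,
)

__all__ = [
    "ADAPTER_5",
    "LINKER",
    "ADAPTER_3",
    "CONSTANT_FLANK",
    "QUERY_LENGTH",
    "BARCODE_LENGTH",
    "OLIGO_LENGTH",
    "Barcode",
    "BarcodePool",
    "OligoRecord",
    "DesignManifest",
    "DesignError",
    "CapacityError",
    "UnresolvableSiteError",
    "barcode_passes_filters",
    "generate_barcode_pool",
    "min_pairwise_hamming",
    "hamming",
    "sanitize_query",
    "orient_query",
    "assemble_oligo",
    "assign_barcodes",
    "dinucleotide_shuffle",
]

ADAPTER_5 = "ACTGGCCGCTTCACTG"
LINKER = "GGTACCTCTAGA"
ADAPTER_3 = "AGATCGGAAGAGCGTCG"
#: first 25 nt downstream of the barcode on the sequencing read
#: (vector/adapter sequence); together with the 10-nt barcode this forms the
#: 35-nt demultiplexing reference unit.
CONSTANT_FLANK = (ADAPTER_3 + "TGTAGGGAAAGAGTGT")[:25]

QUERY_LENGTH = 175
BARCODE_LENGTH = 10
OLIGO_LENGTH = 230
#: genomic flank per side of a centred SNP in the 175-nt query
DESIGN_FLANK_DEFAULT = (QUERY_LENGTH - 1) // 2

KPNI_SITE = "GGTACC"
XBAI_SITE = "TCTAGA"
POLYA_SIGNAL = "AATAAA"
_SFII_RE = re.compile(r"(?=(GGCC[ACGT]{5}GGCC))")
_FORBIDDEN_RES = (
    re.compile(r"(?=(GGTACC))"),
    re.compile(r"(?=(TCTAGA))"),
    _SFII_RE,
)
_HOMOPOLYMER_RE = re.compile(r"A{4,}|C{4,}|G{4,}|T{4,}")

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class DesignError(ValueError):
    pass


class CapacityError(DesignError):
    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could not build {requested} barcodes under the filters; "
            f"achieved {achieved}"
        )
        self.requested = requested
        self.achieved = achieved


class UnresolvableSiteError(DesignError):
    pass


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise DesignError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Barcode:
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != BARCODE_LENGTH or not set(self.sequence) <= set(
            BASES
        ):
            raise DesignError(f"invalid barcode {self.sequence!r}")


@dataclass(frozen=True)
class BarcodePool:
    barcodes: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise DesignError("duplicate barcodes in pool")

    def __len__(self) -> int:
        return len(self.barcodes)


_RC_TABLE = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    # internal fast path: input already validated as A/C/G/T
    return seq.translate(_RC_TABLE)[::-1]


def _has_hairpin(seq: str, min_stem: int = 4, min_loop: int = 3) -> bool:
    """Inverted repeat able to fold back: stem >= min_stem, loop >= min_loop."""
    n = len(seq)
    for stem in range(min_stem, n // 2 + 1):
        for i in range(0, n - 2 * stem - min_loop + 1):
            rc = _rc(seq[i : i + stem])
            for j in range(i + stem + min_loop, n - stem + 1):
                if seq[j : j + stem] == rc:
                    return True
    return False


def _has_palindrome(seq: str, min_len: int = 6) -> bool:
    """Self-reverse-complement substring of >= min_len (even lengths only)."""
    for k in range(min_len + (min_len % 2), len(seq) + 1, 2):
        for i in range(len(seq) - k + 1):
            sub = seq[i : i + k]
            if sub == _rc(sub):
                return True
    return False


@lru_cache(maxsize=128)
def _consensus_regex(pattern: str) -> re.Pattern:
    return re.compile(pattern.replace("N", "."))


def barcode_passes_filters(
    seq: str,
    motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS,
    mirna_seeds: Sequence[str] = (),
    pwms: Sequence[Pwm] = (),
) -> bool:
    """Apply every per-barcode filter.

    Composition filters act on the bare 10-mer: homopolymer runs > 3 bp,
    GC fraction outside [0.30, 0.60], KpnI/XbaI sites, AATAAA, and
    self-complementarity (hairpin/palindrome).  The TF-motif screen runs on
    the barcode flanked by 4 bp of vector context on each side, both
    strands; PWMs in ``pwms`` are screened the same way at their own
    thresholds.  The miRNA screen rejects barcodes containing the reverse
    complement of any supplied 7-nt seed (the transcript-embedded barcode
    would otherwise be a target site).
    """
    if len(seq) != BARCODE_LENGTH or not set(seq) <= set(BASES):
        return False
    if _HOMOPOLYMER_RE.search(seq):
        return False
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if gc > 0.60 or gc < 0.30:
        return False
    for site in (KPNI_SITE, XBAI_SITE, POLYA_SIGNAL):
        if site in seq:
            return False
    if _has_hairpin(seq) or _has_palindrome(seq):
        return False
    flanked = LINKER[-4:] + seq + ADAPTER_3[:4]
    rc_flanked = _rc(flanked)
    for motif in motifs:
        rx = _consensus_regex(motif.pattern)
        if rx.search(flanked) or rx.search(rc_flanked):
            return False
    for pwm in pwms:
        lo = pwm.log_odds()
        for context in (flanked, rc_flanked):
            for i in range(len(context) - pwm.length + 1):
                if _score_window(context[i : i + pwm.length], lo) >= pwm.threshold:
                    return False
    for seed in mirna_seeds:
        if reverse_complement(seed) in seq:
            return False
    return True


def min_pairwise_hamming(barcodes: Sequence[str]) -> int:
    """Exhaustive minimum pairwise Hamming distance over a barcode list."""
    if len(barcodes) < 2:
        raise DesignError("need at least two barcodes")
    codes = np.frombuffer(
        "".join(barcodes).encode(), dtype=np.uint8
    ).reshape(len(barcodes), -1)
    best = codes.shape[1]
    for i in range(len(barcodes) - 1):
        d = (codes[i + 1 :] != codes[i]).sum(axis=1).min()
        best = min(best, int(d))
        if best == 0:
            break
    return best


def generate_barcode_pool(
    n: int,
    seed: int,
    motifs: Sequence[ConsensusMotif] = DEFAULT_MOTIFS,
    mirna_seeds: Sequence[str] = (),
    pwms: Sequence[Pwm] = (),
    min_distance: int = 3,
    max_attempts: int | None = None,
) -> BarcodePool:
    """Sample, filter and distance-thin a pool of ``n`` barcodes.

    Candidates are drawn uniformly from 10-mer space (seeded), passed
    through :func:`barcode_passes_filters`, and accepted greedily only when
    at Hamming distance >= ``min_distance`` from every already-accepted
    barcode.  Deterministic under ``seed``.  Raises :class:`CapacityError`
    when the filters cannot yield ``n`` barcodes within the sampling budget.
    """
    if n < 1:
        raise DesignError("pool size must be >= 1")
    rng = np.random.default_rng(seed)
    budget = max_attempts if max_attempts is not None else 2000 * n + 50000
    use_ball = min_distance == 3
    # two radius-1 Hamming balls intersect iff their centres are within
    # distance 2, so for min_distance 3 a hash of ball members gives O(31)
    # rejection checks per candidate
    ball_members: set[int] = set()
    accepted: list[str] = []
    accepted_codes = np.empty((n, BARCODE_LENGTH), dtype=np.uint8)
    attempts = 0
    while len(accepted) < n and attempts < budget:
        batch = min(8192, budget - attempts)
        draws = rng.integers(0, 4, size=(batch, BARCODE_LENGTH))
        attempts += batch
        seqs = _BASE_BYTES[draws]
        for row, codes in zip(seqs, draws):
            seq = row.tobytes().decode()
            if not barcode_passes_filters(seq, motifs, mirna_seeds, pwms):
                continue
            k = len(accepted)
            if use_ball:
                code = int(sum(int(c) << (2 * i) for i, c in enumerate(codes)))
                ball = _ball1(code)
                if any(b in ball_members for b in ball):
                    continue
                ball_members.update(ball)
            elif k and (accepted_codes[:k] != row).sum(axis=1).min() < min_distance:
                continue
            accepted_codes[k] = row
            accepted.append(seq)
            if len(accepted) == n:
                break
    if len(accepted) < n:
        raise CapacityError(n, len(accepted))
    return BarcodePool(barcodes=tuple(accepted), seed=seed)


def _ball1(code: int) -> list[int]:
    """All 2-bit-per-base encodings within Hamming distance 1 of ``code``."""
    out = [code]
    for i in range(BARCODE_LENGTH):
        cur = (code >> (2 * i)) & 3
        cleared = code & ~(3 << (2 * i))
        for b in range(4):
            if b != cur:
                out.append(cleared | (b << (2 * i)))
    return out


# ---------------------------------------------------------------------------
# Query sanitisation and oligo assembly


def _find_sites(seq: str) -> set[tuple[int, int]]:
    """(start, end) spans of every KpnI/XbaI/SfiI occurrence (with overlap)."""
    sites: set[tuple[int, int]] = set()
    for pat in _FORBIDDEN_RES:
        for m in pat.finditer(seq):
            sites.add((m.start(), m.start() + len(m.group(1))))
    return sites


def sanitize_query(
    query_seq: str, variant_offset: int, max_rounds: int = 100
) -> tuple[str, list[tuple[int, str, str]]]:
    """Remove restriction sites by single-base substitutions.

    While a KpnI (GGTACC), XbaI (TCTAGA) or SfiI (GGCCNNNNNGGCC) occurrence
    remains, the earliest one is edited: candidate positions are tried from
    the base furthest from ``variant_offset`` inward (never the variant base
    itself), and for each the alphabetically first replacement base that
    destroys the occurrence without creating any new site is applied.  All
    edits are returned as (position, from_base, to_base).
    """
    if len(query_seq) != QUERY_LENGTH:
        raise DesignError(
            f"query must be {QUERY_LENGTH} nt, got {len(query_seq)}"
        )
    if not (0 <= variant_offset < len(query_seq)):
        raise DesignError("variant_offset outside the query")
    seq = query_seq
    edits: list[tuple[int, str, str]] = []
    for _ in range(max_rounds):
        sites = _find_sites(seq)
        if not sites:
            break
        start, end = min(sites)
        positions = sorted(
            (p for p in range(start, end) if p != variant_offset),
            key=lambda p: (-abs(p - variant_offset), p),
        )
        remaining = sites - {(start, end)}
        done = False
        for pos in positions:
            for base in BASES:
                if base == seq[pos]:
                    continue
                candidate = seq[:pos] + base + seq[pos + 1 :]
                new_sites = _find_sites(candidate)
                if (start, end) not in new_sites and new_sites <= remaining:
                    edits.append((pos, seq[pos], base))
                    seq = candidate
                    done = True
                    break
            if done:
                break
        if not done:
            raise UnresolvableSiteError(
                f"cannot destroy site at [{start}, {end}) without creating "
                "a new one"
            )
    else:
        raise UnresolvableSiteError("site removal did not converge")
    return seq, edits


def orient_query(
    variant: Variant,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 1000,
) -> str:
    """Cloning strand for a variant's query region.

    Inside any promoter window (TSS +/- halfwidth) the strand of the
    nearest such TSS is used; two equidistant TSSs on opposite strands tie-
    break to "+"; outside promoters the positive genome strand is cloned.
    """
    in_window = [
        g
        for g in genes
        if g.chrom == variant.chrom
        and abs(variant.pos - g.tss) <= promoter_halfwidth
    ]
    if not in_window:
        return "+"
    best = min(abs(variant.pos - g.tss) for g in in_window)
    strands = {g.strand for g in in_window if abs(variant.pos - g.tss) == best}
    return strands.pop() if len(strands) == 1 else "+"


@dataclass(frozen=True)
class OligoRecord:
    query_id: str
    allele: str
    query_seq: str
    barcode: str
    full_seq: str
    edits: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.full_seq) != OLIGO_LENGTH:
            raise DesignError(
                f"oligo must be {OLIGO_LENGTH} nt, got {len(self.full_seq)}"
            )


def assemble_oligo(
    query_id: str,
    allele: str,
    query_seq: str,
    barcode: str,
    edits: Sequence[tuple[int, str, str]] = (),
) -> OligoRecord:
    """Concatenate adapters, query, linker and barcode into the 230-nt oligo."""
    if len(query_seq) != QUERY_LENGTH:
        raise DesignError(f"query must be {QUERY_LENGTH} nt")
    if len(barcode) != BARCODE_LENGTH:
        raise DesignError(f"barcode must be {BARCODE_LENGTH} nt")
    if _find_sites(query_seq):
        raise DesignError("query still contains a forbidden restriction site")
    full = ADAPTER_5 + query_seq + LINKER + barcode + ADAPTER_3
    return OligoRecord(
        query_id=query_id,
        allele=allele,
        query_seq=query_seq,
        barcode=barcode,
        full_seq=full,
        edits=tuple(edits),
    )


# ---------------------------------------------------------------------------
# Barcode assignment / manifest


@dataclass
class DesignManifest:
    """Barcode-to-sequence map, one frame row per (query, allele, barcode)."""

    frame: pd.DataFrame  # columns: query_id, allele, role, barcode

    COLUMNS = ("query_id", "allele", "role", "barcode")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise DesignError(f"manifest missing columns {sorted(missing)}")
        if self.frame["barcode"].duplicated().any():
            raise DesignError("barcode reused across manifest rows")

    @property
    def barcodes(self) -> tuple[str, ...]:
        return tuple(self.frame["barcode"])

    def barcodes_for(self, query_id: str, allele: str) -> tuple[str, ...]:
        sel = (self.frame["query_id"] == query_id) & (
            self.frame["allele"] == allele
        )
        return tuple(self.frame.loc[sel, "barcode"])

    def barcodes_per_row(self) -> pd.Series:
        return self.frame.groupby(["query_id", "allele"], sort=False)[
            "barcode"
        ].size()

    def role_of(self, query_id: str) -> str:
        sel = self.frame.loc[self.frame["query_id"] == query_id, "role"]
        return str(sel.iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DesignManifest":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(frame=frame)


_ROLE_BARCODE_COUNTS = {
    "candidate": 6,
    "positive_ctrl": 3,
    "negative_ctrl": 3,
    "scramble": 3,
    "viral_multimer_ctrl": 3,
}


def assign_barcodes(
    queries: Sequence[tuple[str, str, str]],
    pool: BarcodePool,
    seed: int,
    barcodes_per_role: Mapping[str, int] | None = None,
) -> DesignManifest:
    """Randomly assign pool barcodes to (query_id, allele, role) rows.

    Candidate alleles receive 6 barcodes, controls 3; no barcode is ever
    reused.  Deterministic under ``seed``.  Raises :class:`CapacityError`
    when the pool is too small for the total demand.
    """
    counts = dict(_ROLE_BARCODE_COUNTS)
    if barcodes_per_role:
        counts.update(barcodes_per_role)
    demand = 0
    for _, _, role in queries:
        if role not in counts:
            raise DesignError(f"unknown role {role!r}")
        demand += counts[role]
    if demand > len(pool):
        raise CapacityError(demand, len(pool))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    shuffled = [pool.barcodes[i] for i in order]
    rows = []
    cursor = 0
    for query_id, allele, role in queries:
        k = counts[role]
        for bc in shuffled[cursor : cursor + k]:
            rows.append(
                {"query_id": query_id, "allele": allele, "role": role, "barcode": bc}
            )
        cursor += k
    return DesignManifest(frame=pd.DataFrame(rows, columns=list(DesignManifest.COLUMNS)))


# ---------------------------------------------------------------------------
# Scramble controls


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Eulerian-walk rejection sampling).

    Preserves the exact dinucleotide (and hence mononucleotide) counts of
    the input.  Deterministic under ``rng``.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(5000):
        pools = {v: list(rng.permutation(nb)) for v, nb in edges.items()}
        walk = [seq[0]]
        cur = seq[0]
        for _ in range(n_edges):
            nxt_pool = pools.get(cur)
            if not nxt_pool:
                break
            cur = nxt_pool.pop()
            walk.append(cur)
        if len(walk) == len(seq):
            return "".join(walk)
    raise DesignError("dinucleotide shuffle failed to converge")
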