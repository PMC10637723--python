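"""Allelic and treatment statistics for barcode-based reporter assays.

The allelic test contrasts log2 reporter activity between the two alleles
of a variant.  Because every RNA replicate of a barcode shares the same
DNA-input denominator, per-(barcode, replicate) observations are not
independent across replicates; activities are therefore first averaged
within barcode across the condition's RNA replicates (which also absorbs
replicate effects) and the allele contrast is estimated by ordinary least
squares across barcodes -- an equal-variance two-sample comparison with a
partial-F (equivalently t) p-value.  Fold change is reported as reference
over alternative, so log2FC > 0 means the reference allele is more active.

The treatment test fits, per designed sequence, log2 activity against
condition and replicate over the per-replicate aggregated activities.

Downstream summaries: Benjamini-Hochberg FDR, motif-concordance of
significant allelic effects (is the higher-activity allele the one with the
intact motif?), the Hi/Lo positional-preference matrix over the C/EBP-ATF
10-mer, 2x2 enrichment folds with Fisher exact p-values, and population
allele-frequency divergence flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .motif_scan import BASES, MotifHit, Variant, VariantMotifCall

__all__ = [
    "AllelicResult",
    "PositionPreference",
    "EnrichmentResult",
    "StatsError",
    "floor_zeros",
    "allelic_effect_test",
    "allelic_scan",
    "treatment_effect_test",
    "bh_adjust",
    "concordance",
    "position_preference",
    "enrichment_fold",
    "af_divergence",
]

_COMPLEMENT_1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class AllelicResult:
    rsid: str
    log2fc: float  # reference over alternative
    p_value: float
    fdr: float
    n_ref_barcodes: int
    n_alt_barcodes: int
    floored: bool = False


def floor_zeros(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Replace zero activities by half the smallest positive value."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise StatsError("negative activities are not log-transformable")
    if not (values == 0).any():
        return values, False
    positive = values[values > 0]
    if len(positive) == 0:
        raise StatsError("all activities are zero")
    return np.where(values == 0, positive.min() / 2.0, values), True


def _two_group_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mean difference x - y with the equal-variance OLS/t p-value."""
    diff = float(np.mean(x) - np.mean(y))
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    ss = np.sum((x - np.mean(x)) ** 2) + np.sum((y - np.mean(y)) ** 2)
    if df <= 0:
        return diff, float("nan")
    if ss == 0:
        return diff, 1.0 if diff == 0 else 0.0
    se = np.sqrt(ss / df * (1.0 / nx + 1.0 / ny))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return diff, float(p)


def allelic_effect_test(
    ref_activity: pd.DataFrame | np.ndarray,
    alt_activity: pd.DataFrame | np.ndarray,
    rsid: str = "",
) -> dict:
    """Allelic log2 fold change (ref - alt) and its p-value.

    Inputs are barcode x RNA-sample activity matrices for one condition
    (rows = barcodes of that allele).  Activities are floored, logged,
    averaged within barcode, and contrasted across barcodes.  Fewer than
    two barcodes on either allele makes the variant untestable (NaNs).
    """
    ref = np.atleast_2d(np.asarray(ref_activity, dtype=float))
    alt = np.atleast_2d(np.asarray(alt_activity, dtype=float))
    out = {
        "rsid": rsid,
        "log2fc": np.nan,
        "p_value": np.nan,
        "n_ref_barcodes": ref.shape[0],
        "n_alt_barcodes": alt.shape[0],
        "floored": False,
    }
    if ref.shape[0] < 2 or alt.shape[0] < 2:
        return out
    pooled, floored = floor_zeros(np.concatenate([ref.ravel(), alt.ravel()]))
    nref = ref.size
    ref = pooled[:nref].reshape(ref.shape)
    alt = pooled[nref:].reshape(alt.shape)
    ref_bc = np.log2(ref).mean(axis=1)
    alt_bc = np.log2(alt).mean(axis=1)
    log2fc, p = _two_group_ols(ref_bc, alt_bc)
    out.update({"log2fc": log2fc, "p_value": p, "floored": floored})
    return out


def allelic_scan(
    barcode_activity: pd.DataFrame,
    manifest_frame: pd.DataFrame,
    samples: Sequence,
    condition: str,
    ref_label: str = "ref",
    alt_label: str = "alt",
) -> pd.DataFrame:
    """Allelic tests for every candidate variant in one condition.

    ``barcode_activity`` is the barcode x RNA-sample activity matrix;
    ``manifest_frame`` maps barcodes to (query_id, allele, role).  Returns a
    frame with log2fc, p_value and BH FDR across all testable variants.
    """
    rna_cols = [
        s.sample_id
        for s in samples
        if s.library_type == "RNA" and s.condition == condition
    ]
    if not rna_cols:
        raise StatsError(f"no RNA samples for condition {condition!r}")
    cand = manifest_frame[manifest_frame["role"] == "candidate"]
    rows = []
    for rsid, grp in cand.groupby("query_id", sort=False):
        ref_bcs = [
            b for b in grp.loc[grp["allele"] == ref_label, "barcode"]
            if b in barcode_activity.index
        ]
        alt_bcs = [
            b for b in grp.loc[grp["allele"] == alt_label, "barcode"]
            if b in barcode_activity.index
        ]
        res = allelic_effect_test(
            barcode_activity.loc[ref_bcs, rna_cols],
            barcode_activity.loc[alt_bcs, rna_cols],
            rsid=rsid,
        )
        rows.append(res)
    frame = pd.DataFrame(rows)
    frame["fdr"] = bh_adjust(frame["p_value"].to_numpy())
    return frame


def treatment_effect_test(
    activity: pd.DataFrame,
    samples: Sequence,
    baseline_condition: str | None = None,
) -> pd.DataFrame:
    """Per-sequence treatment effect: log2 activity ~ condition + replicate.

    ``activity`` is the per-sequence activity table ((query_id, allele) x
    RNA sample).  The condition coefficient is treated-over-baseline log2
    fold change.  Sequences absent (NaN or non-positive throughout) in a
    condition are reported with NaNs.
    """
    rna = [s for s in samples if s.library_type == "RNA"]
    conds = sorted({s.condition for s in rna})
    if len(conds) != 2:
        raise StatsError("treatment test requires exactly two conditions")
    if baseline_condition is None:
        baseline_condition = conds[0]
    treated = [c for c in conds if c != baseline_condition][0]
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in rna],
            "condition": [s.condition for s in rna],
            "replicate": [s.replicate for s in rna],
        }
    )
    rows = []
    for key, vals in activity.iterrows():
        obs = meta.assign(activity=vals.loc[meta["sample_id"]].to_numpy())
        obs = obs.dropna(subset=["activity"])
        ok = set(obs["condition"]) == set(conds) and all(
            (obs["condition"] == c).sum() >= 2 for c in conds
        )
        if not ok:
            rows.append({"query_id": key[0], "allele": key[1],
                         "log2fc": np.nan, "p_value": np.nan})
            continue
        floored, _ = floor_zeros(obs["activity"].to_numpy())
        y = np.log2(floored)
        design = pd.DataFrame({"intercept": 1.0}, index=obs.index)
        design["treated"] = (obs["condition"] == treated).astype(float)
        rep_levels = sorted(obs["replicate"].unique())
        for r in rep_levels[1:]:
            design[f"rep_{r}"] = (obs["replicate"] == r).astype(float)
        fit = sm.OLS(y, design).fit()
        coef = float(fit.params["treated"])
        p = float(fit.pvalues["treated"])
        if np.isnan(p):
            p = 1.0 if coef == 0 else 0.0
        rows.append(
            {"query_id": key[0], "allele": key[1], "log2fc": coef, "p_value": p}
        )
    frame = pd.DataFrame(rows)
    frame["fdr"] = bh_adjust(frame["p_value"].to_numpy())
    return frame


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaNs propagate unadjusted."""
    p = np.asarray(list(p_values), dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise StatsError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def concordance(
    allelic: pd.DataFrame,
    calls: Mapping[str, VariantMotifCall],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Motif-concordance of significant allelic effects.

    For motif-disruption variants a significant effect is concordant when
    the higher-activity allele is the motif-intact allele; lenient changes,
    switches and motif-negative variants carry no predicted direction and
    are ``not_applicable``.  The summary also reports, over all variants
    predicted to disrupt a motif, the fraction validated by a significant
    concordant effect.
    """
    rows = []
    n_concordant = n_applicable = 0
    disrupting = {r for r, c in calls.items() if c.category == "disruption"}
    validated = 0
    for _, rec in allelic.iterrows():
        rsid = rec["rsid"]
        call = calls.get(rsid)
        if call is None:
            raise StatsError(f"no motif call for {rsid}")
        significant = (
            not np.isnan(rec["fdr"]) and rec["fdr"] < alpha
            and not np.isnan(rec["log2fc"])
        )
        higher = (
            "ref" if rec["log2fc"] > 0 else "alt" if rec["log2fc"] < 0 else ""
        )
        if call.category == "disruption" and significant and higher:
            verdict = (
                "concordant" if higher == call.intact_allele else "discordant"
            )
            n_applicable += 1
            n_concordant += verdict == "concordant"
            if verdict == "concordant":
                validated += 1
        else:
            verdict = "not_applicable"
        rows.append(
            {
                "rsid": rsid,
                "category": call.category,
                "higher_activity_allele": higher,
                "verdict": verdict,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["rsid", "category", "higher_activity_allele", "verdict"]
    )
    summary = {
        "n_applicable": n_applicable,
        "n_concordant": n_concordant,
        "fraction_concordant": (
            n_concordant / n_applicable if n_applicable else np.nan
        ),
        "n_predicted_disrupting": len(disrupting),
        "fraction_validated": (
            validated / len(disrupting) if disrupting else np.nan
        ),
    }
    return frame, summary


@dataclass
class PositionPreference:
    """Hi/Lo nucleotide counts over the 10 motif positions (rows A,C,G,T)."""

    hi_counts: np.ndarray
    lo_counts: np.ndarray
    log2_ratio: np.ndarray
    preferred_10mer: str
    n_excluded: int = 0


def _oriented_base(base: str, strand: str) -> str:
    return base if strand == "+" else _COMPLEMENT_1[base]


def position_preference(
    significant: pd.DataFrame,
    hits: Iterable[MotifHit],
    variants: Mapping[str, Variant],
    motif_name: str = "CEBP-ATF",
) -> PositionPreference:
    """Hi/Lo base counts at each C/EBP-ATF position from allelic effects.

    For each significant variant with a hit to ``motif_name``, the higher-
    activity allele's base (read in motif-strand orientation) is added to
    the Hi count at the variant's motif position and the lower-activity
    base to Lo.  When both alleles carry hits the position shared between
    them is used (variants without a shared position are excluded); the
    log2 ratio uses a pseudocount of 1 and the preferred 10-mer is the
    per-position argmax, ties reported as N.
    """
    by_variant: dict[str, dict[str, list[MotifHit]]] = {}
    for h in hits:
        if h.motif == motif_name:
            by_variant.setdefault(h.rsid, {}).setdefault(h.allele, []).append(h)
    hi = np.zeros((4, 10), dtype=int)
    lo = np.zeros((4, 10), dtype=int)
    excluded = 0
    for _, rec in significant.iterrows():
        rsid = rec["rsid"]
        if np.isnan(rec["log2fc"]) or rec["log2fc"] == 0:
            continue
        alleles = by_variant.get(rsid)
        if not alleles:
            continue
        if len(alleles) == 2:
            keys_ref = {
                (h.strand, h.offset): h.variant_position_in_motif
                for h in alleles["ref"]
            }
            shared = [
                (pos, strand)
                for (strand, off), pos in keys_ref.items()
                if any(
                    (h.strand, h.offset) == (strand, off)
                    for h in alleles["alt"]
                )
            ]
            if not shared:
                excluded += 1
                continue
            pos, strand = min(shared)
        else:
            (only,) = alleles.values()
            h = min(only, key=lambda h: h.variant_position_in_motif)
            pos, strand = h.variant_position_in_motif, h.strand
        variant = variants[rsid]
        higher = "ref" if rec["log2fc"] > 0 else "alt"
        lower = "alt" if higher == "ref" else "ref"
        hi_base = _oriented_base(variant.allele(higher), strand)
        lo_base = _oriented_base(variant.allele(lower), strand)
        hi[BASES.index(hi_base), pos - 1] += 1
        lo[BASES.index(lo_base), pos - 1] += 1
    ratio = np.log2((hi + 1.0) / (lo + 1.0))
    preferred = []
    for j in range(10):
        col = ratio[:, j]
        top = col.max()
        winners = [BASES[i] for i in range(4) if col[i] == top]
        preferred.append(winners[0] if len(winners) == 1 else "N")
    return PositionPreference(
        hi_counts=hi,
        lo_counts=lo,
        log2_ratio=ratio,
        preferred_10mer="".join(preferred),
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    a: int  # annotated and flagged
    b: int  # annotated
    c: int  # flagged in pool
    d: int  # pool size
    fold: float
    p_value: float


def enrichment_fold(a: int, b: int, c: int, d: int, label: str = "") -> EnrichmentResult:
    """Fold enrichment (a/b)/(c/d) with a two-sided Fisher exact p-value.

    ``a`` annotated-and-flagged, ``b`` annotated, ``c`` flagged in the
    pool, ``d`` pool size.  ``b`` or ``c`` of zero leaves the fold
    undefined (NaN).
    """
    if not (0 <= a <= min(b, c) and b <= d and c <= d):
        raise StatsError("inconsistent 2x2 construction")
    if b == 0 or c == 0:
        return EnrichmentResult(label, a, b, c, d, np.nan, np.nan)
    fold = (a / b) / (c / d)
    table = [[a, b - a], [c - a, d - b - c + a]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(label, a, b, c, d, fold, float(p))


def af_divergence(
    table: pd.DataFrame,
    reference_population: str = "NFE",
    common: float = 0.05,
    rare: float = 0.01,
    fold: float = 5.0,
) -> pd.DataFrame:
    """Population allele-frequency divergence flags per variant.

    ``table`` is rsid x population alternative-allele frequencies.  Flags:
    ``common_and_rare`` -- AF strictly > ``common`` in >= 1 population and
    strictly < ``rare`` in >= 1 other; ``fold_up``/``fold_down`` -- some
    population's AF at least ``fold`` times above/below the reference
    population's.  A zero reference AF leaves ``fold_up`` undefined (NA);
    missing frequencies are skipped per variant.
    """
    if table.shape[1] < 2:
        raise StatsError("need at least two populations")
    if ((table < 0) | (table > 1)).any().any():
        raise StatsError("allele frequencies must lie in [0, 1]")
    if reference_population not in table.columns:
        raise StatsError(f"reference population {reference_population!r} absent")
    out = pd.DataFrame(index=table.index)
    out["common_and_rare"] = [
        bool((row.dropna() > common).any() and (row.dropna() < rare).any())
        for _, row in table.iterrows()
    ]
    others = [c for c in table.columns if c != reference_population]
    fold_up = []
    fold_down = []
    for _, row in table.iterrows():
        ref_af = row[reference_population]
        vals = row[others].dropna()
        if pd.isna(ref_af) or len(vals) == 0:
            fold_up.append(pd.NA)
            fold_down.append(pd.NA)
            continue
        if ref_af == 0:
            fold_up.append(pd.NA)
        else:
            fold_up.append(bool((vals / ref_af >= fold).any()))
        fold_down.append(bool((vals <= ref_af / fold).any()))
    out["fold_up"] = pd.array(fold_up, dtype="boolean")
    out["fold_down"] = pd.array(fold_down, dtype="boolean")
    return out
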