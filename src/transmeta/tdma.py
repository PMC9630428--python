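"""Trans-disease meta-analysis (TDMA) of two harmonized GWAS.

The TDMA statistic is a fixed, equally weighted combination of two traits'
per-marker effects:

    shared:    beta = (beta1 + beta2) / 2
    opposing:  beta = (beta2 - beta1) / 2
    variance:  V    = (se1^2 + se2^2) / 4

so a marker whose allele raises risk in both traits scores highly in the
shared scan, and one that raises risk in trait 2 while lowering it in
trait 1 scores highly in the opposing scan (trait 2 carries the positive
sign by convention, configurable by swapping inputs).  A region is reported
as a shared/opposing locus only when three criteria hold simultaneously:
(i) the TDMA p-value is genome-wide significant, (ii) each individual trait
is at least suggestively significant, and (iii) the TDMA p-value beats both
single-trait p-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

#: default locus-calling thresholds
GENOMEWIDE_P = 5e-8
SUGGESTIVE_P = 1e-4
MIN_SEPARATION_BP = 500_000
#: extended MHC interval excluded (complex LD), 1-based inclusive
MHC_REGION = ("6", 25_000_000, 34_000_000)

TDMA_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "EAF1", "EAF2", "MODE",
    "BETA_TDMA", "SE_TDMA", "Z", "P_TDMA", "P1", "P2", "MORE_SIGNIFICANT",
]


@dataclass(frozen=True)
class Locus:
    """A called shared/opposing locus with its lead marker and window."""

    lead_marker: str
    chrom: str
    lead_pos: int
    mode: str
    p_tdma: float
    p1: float
    p2: float
    window: tuple[int, int]
    member_markers: tuple[str, ...] = ()
    criteria_flags: dict = field(
        default_factory=lambda: {
            "genomewide_tdma": True,
            "suggestive_both": True,
            "tdma_more_significant": True,
        }
    )


def two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal tail probability, clipped into (0, 1]."""
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def tdma_combine(
    pairs: pd.DataFrame,
    mode: str = "shared",
    orient_risk: bool = True,
) -> pd.DataFrame:
    """Compute the TDMA statistic for every harmonized marker pair.

    Parameters
    ----------
    pairs
        Harmonized table from :func:`transmeta.sumstats.harmonize` (columns
        ``BETA1 SE1 P1 BETA2 SE2 P2`` on a common effect allele).
    mode
        ``"shared"`` for same-direction effects, ``"opposing"`` for
        opposite-direction effects (trait 2 positive).
    orient_risk
        When True, markers are re-oriented so the reported TDMA effect is
        non-negative: the allele columns are swapped and allele frequencies
        complemented on flipped markers, matching risk-allele reporting.

    Markers with missing or nonpositive SE in either trait are skipped.
    """
    if mode not in ("shared", "opposing"):
        raise ValueError(f"mode must be 'shared' or 'opposing', got {mode!r}")
    df = pairs.copy()
    usable = (df["SE1"] > 0) & (df["SE2"] > 0)
    usable &= df["BETA1"].notna() & df["BETA2"].notna()
    df = df[usable.fillna(False)]

    b1 = df["BETA1"].to_numpy(dtype=float)
    b2 = df["BETA2"].to_numpy(dtype=float)
    beta = (b1 + b2) / 2.0 if mode == "shared" else (b2 - b1) / 2.0
    var = (df["SE1"].to_numpy(dtype=float) ** 2 + df["SE2"].to_numpy(dtype=float) ** 2) / 4.0
    se = np.sqrt(var)
    z = beta / se
    p = two_sided_p(z)

    a1 = df["A1"].to_numpy(dtype=object)
    a2 = df["A2"].to_numpy(dtype=object)
    eaf1 = df["EAF1"].to_numpy(dtype=float) if "EAF1" in df else np.full(len(df), np.nan)
    eaf2 = df["EAF2"].to_numpy(dtype=float) if "EAF2" in df else np.full(len(df), np.nan)
    if orient_risk:
        neg = beta < 0
        beta = np.where(neg, -beta, beta)
        z = np.where(neg, -z, z)
        a1, a2 = np.where(neg, a2, a1), np.where(neg, a1, a2)
        eaf1 = np.where(neg, 1.0 - eaf1, eaf1)
        eaf2 = np.where(neg, 1.0 - eaf2, eaf2)

    p1 = df["P1"].to_numpy(dtype=float)
    p2 = df["P2"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "SNP": df["SNP"].to_numpy(),
            "CHR": df["CHR"].astype(str).to_numpy(),
            "BP": df["BP"].to_numpy(dtype=np.int64),
            "A1": a1, "A2": a2, "EAF1": eaf1, "EAF2": eaf2,
            "MODE": mode,
            "BETA_TDMA": beta, "SE_TDMA": se, "Z": z, "P_TDMA": p,
            "P1": p1, "P2": p2,
            "MORE_SIGNIFICANT": p < np.minimum(p1, p2),
        },
        columns=TDMA_COLUMNS,
    )


def count_more_significant(results: pd.DataFrame) -> int:
    """Number of markers whose TDMA p-value beats both single-trait p-values."""
    if results.empty:
        return 0
    return int((results["P_TDMA"] < np.minimum(results["P1"], results["P2"])).sum())


def call_loci(
    results: pd.DataFrame,
    gw: float = GENOMEWIDE_P,
    suggestive: float = SUGGESTIVE_P,
    min_sep_bp: int = MIN_SEPARATION_BP,
    exclude_mhc: bool = False,
    mhc_region: tuple[str, int, int] = MHC_REGION,
) -> list[Locus]:
    """Greedy distance-based locus calling under the three TDMA criteria.

    Candidate lead markers must satisfy ``P_TDMA < gw``, ``P1 < suggestive``,
    ``P2 < suggestive`` and ``P_TDMA < min(P1, P2)``.  Candidates are visited
    in order of ascending TDMA p (ties broken by chromosome then position);
    a candidate becomes a lead unless an accepted lead on the same chromosome
    lies within ``min_sep_bp``.  Each locus window is lead +/- min_sep_bp/2,
    1-based inclusive.
    """
    if results.empty:
        return []
    df = results
    eligible = (
        (df["P_TDMA"] < gw)
        & (df["P1"] < suggestive)
        & (df["P2"] < suggestive)
        & (df["P_TDMA"] < np.minimum(df["P1"], df["P2"]))
    )
    if exclude_mhc:
        chrom, start, end = mhc_region
        in_mhc = (df["CHR"].astype(str) == str(chrom)) & df["BP"].between(start, end)
        eligible &= ~in_mhc
    cand = df[eligible].sort_values(["P_TDMA", "CHR", "BP"], kind="mergesort")

    half = min_sep_bp // 2
    leads: list[tuple[str, int]] = []
    loci: list[Locus] = []
    for row in cand.itertuples(index=False):
        if any(c == row.CHR and abs(p - row.BP) < min_sep_bp for c, p in leads):
            continue
        leads.append((row.CHR, int(row.BP)))
        lo, hi = int(row.BP) - half, int(row.BP) + half
        members = df[(df["CHR"] == row.CHR) & df["BP"].between(lo, hi)]
        loci.append(
            Locus(
                lead_marker=row.SNP,
                chrom=str(row.CHR),
                lead_pos=int(row.BP),
                mode=str(row.MODE),
                p_tdma=float(row.P_TDMA),
                p1=float(row.P1),
                p2=float(row.P2),
                window=(lo, hi),
                member_markers=tuple(members["SNP"]),
            )
        )
    return loci


def loci_to_frame(loci: Iterable[Locus]) -> pd.DataFrame:
    rows = [
        {
            "SNP": l.lead_marker, "CHR": l.chrom, "BP": l.lead_pos, "MODE": l.mode,
            "P_TDMA": l.p_tdma, "P1": l.p1, "P2": l.p2,
            "WINDOW_START": l.window[0], "WINDOW_END": l.window[1],
            "N_MARKERS": len(l.member_markers),
        }
        for l in loci
    ]
    return pd.DataFrame(
        rows,
        columns=["SNP", "CHR", "BP", "MODE", "P_TDMA", "P1", "P2",
                 "WINDOW_START", "WINDOW_END", "N_MARKERS"],
    )


def loci_to_bed(loci: Iterable[Locus]) -> pd.DataFrame:
    """Locus windows as BED (0-based half-open, from 1-based inclusive)."""
    rows = [
        {
            "chrom": l.chrom,
            "chromStart": max(0, l.window[0] - 1),
            "chromEnd": l.window[1],
            "name": f"{l.lead_marker}:{l.mode}",
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=["chrom", "chromStart", "chromEnd", "name"])


def loci_report(loci: Iterable[Locus]) -> str:
    """JSON locus report (lead, mode, window, criteria flags, members)."""
    payload = [
        {
            "lead_marker": l.lead_marker, "chrom": l.chrom, "lead_pos": l.lead_pos,
            "mode": l.mode, "p_tdma": l.p_tdma, "p1": l.p1, "p2": l.p2,
            "window": list(l.window), "n_members": len(l.member_markers),
            "criteria_flags": l.criteria_flags,
        }
        for l in loci
    ]
    return json.dumps(payload, indent=2)
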