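"""Reading, validation and cross-trait harmonization of GWAS summary statistics.

A summary-statistic table is carried as a :class:`pandas.DataFrame` with the
canonical columns ``SNP CHR BP A1 A2 BETA SE P EAF N`` (``EAF`` and ``N``
optional).  ``A1`` is the effect allele: ``BETA`` is the per-``A1``-allele
log-odds ratio (or linear effect) and ``EAF`` its frequency.  Harmonization
re-expresses a second trait's effects on the first trait's effect allele so
that per-marker effects can be combined across traits.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for the on-disk dialect
CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "EAF", "N")
REQUIRED_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: relative tolerance for the |beta/se| vs p-derived |z| consistency check;
#: generous because published p-values are typically rounded to 2 significant digits
Z_P_RTOL = 0.10

#: p-values below this are beyond the resolution of a printed table and the
#: normal quantile is numerically unreliable, so the z-vs-p check is skipped
_Z_P_CHECK_FLOOR = 1e-250


class SumstatsError(ValueError):
    """Configuration-level problem with a summary-statistics input."""


@dataclass(frozen=True)
class VariantRecord:
    """One marker's association summary for a single trait."""

    marker_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.marker_id}: nonpositive SE")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.marker_id}: p outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.marker_id}: EAF outside (0, 1)")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class HarmonizePolicy:
    """How to align a second trait onto the first trait's effect alleles.

    ``palindromic`` is one of ``"rescue"`` (keep strand-ambiguous A/T, C/G
    markers only when both traits' allele frequencies fall outside
    ``ambiguous_eaf_range`` and resolve the strand), ``"drop"`` (always drop
    them) or ``"keep"`` (assume same strand).  ``key`` selects the join key:
    ``"snp"`` for the marker id, ``"chrom_pos"`` for chromosome:position with
    sorted alleles as a fallback identity.
    """

    palindromic: str = "rescue"
    ambiguous_eaf_range: tuple[float, float] = (0.42, 0.58)
    key: str = "snp"

    def __post_init__(self) -> None:
        if self.palindromic not in ("rescue", "drop", "keep"):
            raise SumstatsError(f"unknown palindromic policy {self.palindromic!r}")
        if self.key not in ("snp", "chrom_pos"):
            raise SumstatsError(f"unknown join key {self.key!r}")


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    drop_invalid: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a whitespace/tab-delimited summary-statistics table.

    Parameters
    ----------
    path
        File path; ``.gz`` handled transparently.
    column_map
        Maps canonical names (``SNP``, ``CHR``, ...) to the names used in the
        file header.  Canonical names absent from the map are assumed to be
        literal column names.
    drop_invalid
        When True (default), rows failing validation are removed and returned
        in the reject table; when False a nonempty reject table raises.

    Returns
    -------
    (table, rejects)
        ``table`` holds validated rows in input order under canonical column
        names; ``rejects`` has columns ``SNP`` and ``reason``.
    """
    column_map = dict(column_map or {})
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=r"\s+", dtype=str)
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsError(f"missing required column(s): {', '.join(missing)}")

    df = raw.copy()
    for col in ("BETA", "SE", "P", "EAF"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["BP"] = pd.to_numeric(df["BP"], errors="coerce")
    if "N" in df.columns:
        df["N"] = pd.to_numeric(df["N"], errors="coerce")
    df["CHR"] = df["CHR"].astype(str)
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()

    valid, rejects = validate_sumstats(df)
    if rejects.shape[0] and not drop_invalid:
        raise SumstatsError(f"{rejects.shape[0]} invalid row(s); first: {rejects.iloc[0]['reason']}")
    if rejects.shape[0]:
        logger.warning("dropped %d invalid row(s) from %s", rejects.shape[0], path)
    valid["BP"] = valid["BP"].astype(np.int64)
    cols = [c for c in CANONICAL_COLUMNS if c in valid.columns]
    return valid[cols].reset_index(drop=True), rejects


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a table into valid rows and rejects with per-row reasons.

    Checks: numeric beta/se/p, se > 0, p in (0, 1], EAF in (0, 1) when
    present, position present, and agreement between |beta/se| and the |z|
    implied by the two-sided p (within ``Z_P_RTOL`` relative, skipped for
    p-values too small to invert reliably).
    """
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    flag(df["BETA"].isna() | df["SE"].isna() | df["P"].isna(), "non-numeric beta/se/p")
    flag(df["BP"].isna(), "missing position")
    flag(df["SE"] <= 0, "nonpositive SE")
    flag((df["P"] <= 0) | (df["P"] > 1), "p outside (0,1]")
    if "EAF" in df.columns:
        bad_eaf = df["EAF"].notna() & ((df["EAF"] <= 0) | (df["EAF"] >= 1))
        flag(bad_eaf, "EAF outside (0,1)")

    ok = reasons == ""
    with np.errstate(divide="ignore", invalid="ignore"):
        z_obs = np.abs(df["BETA"] / df["SE"])
        z_p = np.abs(stats.norm.isf(np.clip(df["P"], 1e-320, 1.0) / 2.0))
    checkable = ok & (df["P"] > _Z_P_CHECK_FLOOR) & (df["P"] < 1.0) & (z_p > 0)
    mismatch = checkable & (np.abs(z_obs - z_p) > Z_P_RTOL * z_p)
    flag(mismatch, "z inconsistent with p")

    ok = reasons == ""
    rejects = pd.DataFrame({"SNP": df.loc[~ok, "SNP"], "reason": reasons[~ok]})
    return df[ok].copy(), rejects.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a table in the canonical tab-delimited dialect (gzip by suffix).

    Floats are written with 10 significant digits so a write/read round trip
    reproduces values to printed precision.
    """
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    with _open_text(path, "wt") as fh:
        df[cols].to_csv(fh, sep="\t", index=False, float_format="%.10g")


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = [
        {
            "SNP": r.marker_id, "CHR": r.chrom, "BP": r.pos,
            "A1": r.effect_allele, "A2": r.other_allele,
            "BETA": r.beta, "SE": r.se, "P": r.p,
            "EAF": np.nan if r.eaf is None else r.eaf,
            "N": np.nan if r.n is None else r.n,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[VariantRecord]:
    out = []
    for row in df.itertuples(index=False):
        eaf = getattr(row, "EAF", np.nan)
        n = getattr(row, "N", np.nan)
        out.append(
            VariantRecord(
                marker_id=row.SNP, chrom=str(row.CHR), pos=int(row.BP),
                effect_allele=row.A1, other_allele=row.A2,
                beta=float(row.BETA), se=float(row.SE), p=float(row.P),
                eaf=None if pd.isna(eaf) else float(eaf),
                n=None if pd.isna(n) else int(n),
            )
        )
    return out


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return _COMPLEMENT.get(a1) == a2 if len(a1) == 1 and len(a2) == 1 else False


def _complement_allele(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def _dedupe(df: pd.DataFrame, key: str) -> pd.DataFrame:
    # duplicated join keys: keep the smallest-p copy (deterministic, conservative)
    dup = df.duplicated(subset=key, keep=False)
    if not dup.any():
        return df
    logger.warning("%d duplicated marker id(s); keeping smallest p", df.loc[dup, key].nunique())
    return (
        df.sort_values(["P", key], kind="mergesort")
        .drop_duplicates(subset=key, keep="first")
        .sort_index()
    )


def harmonize(
    a: pd.DataFrame,
    b: pd.DataFrame,
    policy: HarmonizePolicy | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align trait b's effects onto trait a's effect alleles.

    Only markers present in both inputs are kept.  Where b reports the swapped
    allele pair, its beta is negated and its EAF complemented; strand flips
    (complementary alleles) are resolved; strand-ambiguous markers are handled
    per ``policy``.  Irreconcilable allele pairs are dropped.

    Returns
    -------
    (pairs, drops)
        ``pairs`` has columns ``SNP CHR BP A1 A2 BETA1 SE1 P1 EAF1 BETA2 SE2
        P2 EAF2 FLIP``; ``drops`` has ``SNP`` and ``reason`` in
        {palindromic, allele_mismatch, duplicate}.
    """
    policy = policy or HarmonizePolicy()

    def keyed(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        if "EAF" not in df.columns:
            df["EAF"] = np.nan
        if policy.key == "snp":
            df["_KEY"] = df["SNP"]
        else:
            alleles = np.sort(df[["A1", "A2"]].to_numpy(), axis=1)
            df["_KEY"] = (
                df["CHR"].astype(str) + ":" + df["BP"].astype(str)
                + ":" + alleles[:, 0] + ":" + alleles[:, 1]
            )
        return df

    a = keyed(a)
    b = keyed(b)
    drops: list[tuple[str, str]] = []
    for df in (a, b):
        n_before = df.shape[0]
        deduped = _dedupe(df, "_KEY")
        if deduped.shape[0] < n_before:
            gone = df.loc[~df.index.isin(deduped.index), "SNP"]
            drops.extend((snp, "duplicate") for snp in gone)
        df.drop(df.index.difference(deduped.index), inplace=True)

    merged = a.merge(b, on="_KEY", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        return _empty_pairs(), pd.DataFrame(drops, columns=["SNP", "reason"])

    a1a = merged["A1_a"].to_numpy()
    a2a = merged["A2_a"].to_numpy()
    a1b = merged["A1_b"].to_numpy()
    a2b = merged["A2_b"].to_numpy()
    beta2 = merged["BETA_b"].to_numpy(dtype=float).copy()
    eaf2 = merged["EAF_b"].to_numpy(dtype=float).copy() if "EAF_b" in merged else np.full(len(merged), np.nan)
    eaf1 = merged["EAF_a"].to_numpy(dtype=float) if "EAF_a" in merged else np.full(len(merged), np.nan)

    flip = np.zeros(len(merged), dtype=bool)
    keep = np.ones(len(merged), dtype=bool)
    reason = np.array(["none"] * len(merged), dtype=object)

    comp1b = np.array([_complement_allele(x) or "?" for x in a1b])
    comp2b = np.array([_complement_allele(x) or "?" for x in a2b])

    same = (a1a == a1b) & (a2a == a2b)
    swapped = (a1a == a2b) & (a2a == a1b)
    strand_same = (a1a == comp1b) & (a2a == comp2b)
    strand_swapped = (a1a == comp2b) & (a2a == comp1b)
    palin = np.array([is_palindromic(x, y) for x, y in zip(a1a, a2a)])

    matchable = same | swapped | strand_same | strand_swapped
    keep &= matchable
    reason[~matchable] = "allele_mismatch"

    # unambiguous markers: a swap (directly or after strand complement) flips
    plain_flip = ~palin & matchable & (swapped | (strand_swapped & ~strand_same))
    flip[plain_flip] = True

    if policy.palindromic == "drop":
        keep &= ~palin
        reason[palin & matchable] = "palindromic"
    elif policy.palindromic == "rescue":
        lo, hi = policy.ambiguous_eaf_range
        informative = (
            ~np.isnan(eaf1) & ~np.isnan(eaf2)
            & ((eaf1 < lo) | (eaf1 > hi)) & ((eaf2 < lo) | (eaf2 > hi))
        )
        rescue_fail = palin & matchable & ~informative
        keep &= ~rescue_fail
        reason[rescue_fail] = "palindromic"
        # discordant minor allele implies opposite strands: flip
        discordant = palin & matchable & informative & ((eaf1 < 0.5) != (eaf2 < 0.5))
        flip[discordant] = True
    # policy "keep": palindromic treated like same/swapped above

    beta2[flip] = -beta2[flip]
    eaf2[flip] = 1.0 - eaf2[flip]

    drops.extend(zip(merged.loc[~keep, "SNP_a"], reason[~keep]))
    out = pd.DataFrame(
        {
            "SNP": merged["SNP_a"], "CHR": merged["CHR_a"].astype(str),
            "BP": merged["BP_a"].astype(np.int64),
            "A1": a1a, "A2": a2a,
            "BETA1": merged["BETA_a"].astype(float), "SE1": merged["SE_a"].astype(float),
            "P1": merged["P_a"].astype(float), "EAF1": eaf1,
            "BETA2": beta2, "SE2": merged["SE_b"].astype(float),
            "P2": merged["P_b"].astype(float), "EAF2": eaf2,
            "FLIP": flip,
        }
    )[keep].reset_index(drop=True)
    return out, pd.DataFrame(drops, columns=["SNP", "reason"])


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "SNP", "CHR", "BP", "A1", "A2",
            "BETA1", "SE1", "P1", "EAF1",
            "BETA2", "SE2", "P2", "EAF2", "FLIP",
        ]
    )


def split_pairs(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`harmonize`: recover the two single-trait tables."""
    base = pairs[["SNP", "CHR", "BP", "A1", "A2"]]
    t1 = base.assign(BETA=pairs["BETA1"], SE=pairs["SE1"], P=pairs["P1"], EAF=pairs["EAF1"])
    t2 = base.assign(BETA=pairs["BETA2"], SE=pairs["SE2"], P=pairs["P2"], EAF=pairs["EAF2"])
    return t1, t2
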