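"""Synthetic paired GWAS summary statistics and MR scenarios with known truth.

The generator works entirely at the summary level, mirroring what the
pipeline consumes.  Markers sit on a chromosome in LD blocks with AR(1)
correlation; per-marker standard errors follow the usual GWAS approximation
se ~ 1/sqrt(2 N maf (1-maf)) with N an effective sample size.  Z-scores are
drawn from the standard summary-statistic model z ~ N(R lambda, R), where R
is the block LD matrix and lambda carries the planted causal effects
(lambda_c = beta_c / se_c at each causal marker).  The two traits share the
marker map and LD structure but have independent noise, as for two GWAS on
disjoint samples.

Planted locus types: ``shared`` (same-direction effect in both traits),
``opposing`` (opposite directions), ``trait1_only``, ``trait2_only`` and
``null``.  Default effect magnitudes put each affected trait's causal marker
at |z| ~ 6.5, the strength regime of loci that are suggestively significant
in both traits and genome-wide significant when combined.

MR scenarios draw instrument exposure effects from N(0, sigma_x^2), add
measurement noise at the exposure and outcome SEs, and generate outcome
effects theta * beta_true + alpha + noise with alpha an optional balanced or
directional pleiotropy term; winner's-curse selection is reproduced by
truncating on the observed exposure p-value (flag-controlled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mr import INSTRUMENT_P_THRESHOLD, InstrumentSet
from .tdma import MIN_SEPARATION_BP, two_sided_p

LOCUS_KINDS = ("shared", "opposing", "trait1_only", "trait2_only", "null")

#: non-palindromic allele pairs assigned to simulated markers
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: default planted per-trait |z| at the causal marker
DEFAULT_PLANTED_Z = 6.5
#: effective sample sizes emulating an ~11k/16k case-control study (trait 1)
#: and a ~61k/124k study (trait 2): n_eff = 4 / (1/n_case + 1/n_control)
DEFAULT_N1 = 26_000
DEFAULT_N2 = 160_000


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LocusPlan:
    """One planted locus: its type, position and per-trait log-OR.

    Either give ``beta1``/``beta2`` directly, or ``z1``/``z2`` target
    noncentralities to be converted using the causal marker's SE (so the
    planted strength is invariant to the drawn allele frequency).
    """

    kind: str
    pos: int
    chrom: str = "1"
    beta1: float | None = None
    beta2: float | None = None
    z1: float | None = None
    z2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in LOCUS_KINDS:
            raise SimConfigError(f"unknown locus kind {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one paired-sumstats draw; the seed fixes everything."""

    seed: int
    n_markers: int = 6000
    spacing_bp: int = 500
    block_size: int = 50
    rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n1: int = DEFAULT_N1
    n2: int = DEFAULT_N2
    loci: tuple[LocusPlan, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise SimConfigError("rho must be in [0, 1)")
        positions = sorted(l.pos for l in self.loci)
        for a, b in zip(positions, positions[1:]):
            if b - a < MIN_SEPARATION_BP:
                raise SimConfigError(
                    f"planted loci at {a} and {b} are closer than {MIN_SEPARATION_BP} bp"
                )


def default_locus_plan(
    planted_z: float = DEFAULT_PLANTED_Z,
    start_pos: int = 250_000,
    sep_bp: int = MIN_SEPARATION_BP,
) -> tuple[LocusPlan, ...]:
    """One locus of each type plus a second null, 500 kb apart.

    Opposing loci follow the trait-2-positive sign convention: the planted
    allele lowers trait-1 risk and raises trait-2 risk.
    """
    kinds_and_z = [
        ("shared", planted_z, planted_z),
        ("opposing", -planted_z, planted_z),
        ("trait1_only", planted_z, 0.0),
        ("trait2_only", 0.0, planted_z),
        ("null", 0.0, 0.0),
        ("null", 0.0, 0.0),
    ]
    return tuple(
        LocusPlan(kind=k, pos=start_pos + i * sep_bp, z1=z1, z2=z2)
        for i, (k, z1, z2) in enumerate(kinds_and_z)
    )


def default_config(seed: int) -> SimConfig:
    return SimConfig(seed=seed, loci=default_locus_plan())


def _block_slices(n: int, block: int):
    for start in range(0, n, block):
        yield slice(start, min(start + block, n))


def _ar1_matrix(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ld_matrix(cfg: SimConfig, snps: list[str] | None = None,
              all_snps: list[str] | None = None) -> pd.DataFrame:
    """Signed LD (r) implied by the block-AR(1) structure.

    Markers in different blocks have r = 0.  ``all_snps`` gives the full
    marker order (defaults to the canonical simulated ids); ``snps``
    restricts the output to a subset.
    """
    if all_snps is None:
        all_snps = [f"snp{i:06d}" for i in range(cfg.n_markers)]
    index = {s: i for i, s in enumerate(all_snps)}
    snps = list(snps) if snps is not None else list(all_snps)
    pos = np.array([index[s] for s in snps])
    same_block = (pos[:, None] // cfg.block_size) == (pos[None, :] // cfg.block_size)
    r = np.where(same_block, cfg.rho ** np.abs(pos[:, None] - pos[None, :]), 0.0)
    return pd.DataFrame(r, index=snps, columns=snps)


def simulate_pair_sumstats(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw paired summary statistics and the planted-truth table.

    Returns two canonical sumstats tables (already on a common effect
    allele) and a truth table with one row per planted locus: kind, chrom,
    the causal marker's id/position, and the planted per-trait log-ORs and
    noncentralities.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_markers
    pos = (np.arange(n) + 1) * cfg.spacing_bp
    maf = rng.uniform(*cfg.maf_range, size=n)
    se1 = 1.0 / np.sqrt(2.0 * cfg.n1 * maf * (1.0 - maf))
    se2 = 1.0 / np.sqrt(2.0 * cfg.n2 * maf * (1.0 - maf))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snps = np.array([f"snp{i:06d}" for i in range(n)])

    lam1 = np.zeros(n)
    lam2 = np.zeros(n)
    truth_rows = []
    for plan in cfg.loci:
        c = int(np.argmin(np.abs(pos - plan.pos)))
        b1 = plan.beta1 if plan.beta1 is not None else (plan.z1 or 0.0) * se1[c]
        b2 = plan.beta2 if plan.beta2 is not None else (plan.z2 or 0.0) * se2[c]
        lam1[c] = b1 / se1[c]
        lam2[c] = b2 / se2[c]
        truth_rows.append(
            {
                "kind": plan.kind, "chrom": plan.chrom, "pos": int(pos[c]),
                "snp": snps[c], "beta1": b1, "beta2": b2,
                "z1": lam1[c], "z2": lam2[c],
            }
        )

    z1 = np.empty(n)
    z2 = np.empty(n)
    chol_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for sl in _block_slices(n, cfg.block_size):
        size = sl.stop - sl.start
        if size not in chol_cache:
            R = _ar1_matrix(size, cfg.rho)
            chol_cache[size] = (R, np.linalg.cholesky(R))
        R, L = chol_cache[size]
        z1[sl] = R @ lam1[sl] + L @ rng.standard_normal(size)
        z2[sl] = R @ lam2[sl] + L @ rng.standard_normal(size)

    def table(z, se, n_eff):
        return pd.DataFrame(
            {
                "SNP": snps, "CHR": "1", "BP": pos.astype(np.int64),
                "A1": a1, "A2": a2,
                "BETA": z * se, "SE": se, "P": two_sided_p(z),
                "EAF": maf, "N": n_eff,
            }
        )

    truth = pd.DataFrame(
        truth_rows, columns=["kind", "chrom", "pos", "snp", "beta1", "beta2", "z1", "z2"]
    )
    return table(z1, se1, cfg.n1), table(z2, se2, cfg.n2), truth


def simulate_locus_pair(
    seed: int,
    n_markers: int = 200,
    rho: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n1: int = DEFAULT_N1,
    n2: int = DEFAULT_N2,
    causal1: int | None = None,
    causal2: int | None = None,
    z1: float = DEFAULT_PLANTED_Z,
    z2: float = DEFAULT_PLANTED_Z,
    spacing_bp: int = 500,
) -> pd.DataFrame:
    """One locus, two traits, arbitrary causal placement (harmonized table).

    Unlike :func:`simulate_pair_sumstats`, the two causal markers may sit
    anywhere in the locus — including the same marker (the colocalizing
    case) or two distinct markers (the linkage case).  The whole locus is a
    single AR(1) LD block.  ``causal1``/``causal2`` are marker indices
    (None plants no effect for that trait).  Returns columns
    ``SNP CHR BP BETA1 SE1 P1 BETA2 SE2 P2 BETA_TDMA SE_TDMA`` with the
    shared-mode combined statistic precomputed.
    """
    rng = np.random.default_rng(seed)
    pos = (np.arange(n_markers) + 1) * spacing_bp
    maf = rng.uniform(*maf_range, size=n_markers)
    se1 = 1.0 / np.sqrt(2.0 * n1 * maf * (1.0 - maf))
    se2 = 1.0 / np.sqrt(2.0 * n2 * maf * (1.0 - maf))
    R = _ar1_matrix(n_markers, rho)
    L = np.linalg.cholesky(R)
    lam1 = np.zeros(n_markers)
    lam2 = np.zeros(n_markers)
    if causal1 is not None:
        lam1[causal1] = z1
    if causal2 is not None:
        lam2[causal2] = z2
    zs1 = R @ lam1 + L @ rng.standard_normal(n_markers)
    zs2 = R @ lam2 + L @ rng.standard_normal(n_markers)
    b1, b2 = zs1 * se1, zs2 * se2
    beta_tdma = (b1 + b2) / 2.0
    se_tdma = np.sqrt((se1**2 + se2**2) / 4.0)
    return pd.DataFrame(
        {
            "SNP": [f"snp{i:06d}" for i in range(n_markers)],
            "CHR": "1", "BP": pos.astype(np.int64),
            "BETA1": b1, "SE1": se1, "P1": two_sided_p(zs1),
            "BETA2": b2, "SE2": se2, "P2": two_sided_p(zs2),
            "BETA_TDMA": beta_tdma, "SE_TDMA": se_tdma,
        }
    )


@dataclass(frozen=True)
class MRSimConfig:
    """Conditions for one two-sample MR scenario draw."""

    seed: int
    n_instruments: int = 448
    theta: float = 0.0
    sigma_x: float = 0.05
    se_exp: float = 0.01
    se_out: float = 0.025
    pleiotropy: str = "none"  # none | balanced | directional
    pleio_sd: float = 0.0
    pleio_mean: float = 0.0
    winners_curse: bool = True
    p_threshold: float = INSTRUMENT_P_THRESHOLD

    def __post_init__(self) -> None:
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise SimConfigError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.pleiotropy == "directional" and self.pleio_mean == 0.0:
            raise SimConfigError("directional pleiotropy needs a nonzero pleio_mean")


def simulate_mr_scenario(cfg: MRSimConfig) -> tuple[InstrumentSet, dict]:
    """Draw a harmonized instrument table and its generating truth.

    True exposure effects are N(0, sigma_x^2); the observed exposure effect
    adds N(0, se_exp^2) noise and, with ``winners_curse`` on, instruments
    are kept only if the observed exposure p passes ``p_threshold``
    (rejection sampling), reproducing selection bias.  Outcome effects are
    theta * beta_true + alpha + N(0, se_out^2) with alpha ~ 0 (none),
    N(0, pleio_sd^2) (balanced) or N(pleio_mean, pleio_sd^2) (directional).
    """
    rng = np.random.default_rng(cfg.seed)
    from scipy import stats as _st

    z_thresh = float(_st.norm.isf(cfg.p_threshold / 2.0))
    kept_true: list[np.ndarray] = []
    kept_obs: list[np.ndarray] = []
    n_kept = 0
    while n_kept < cfg.n_instruments:
        batch = max(64, 2 * (cfg.n_instruments - n_kept))
        b_true = rng.normal(0.0, cfg.sigma_x, size=batch)
        b_obs = b_true + rng.normal(0.0, cfg.se_exp, size=batch)
        if cfg.winners_curse:
            sel = np.abs(b_obs / cfg.se_exp) >= z_thresh
            b_true, b_obs = b_true[sel], b_obs[sel]
        kept_true.append(b_true)
        kept_obs.append(b_obs)
        n_kept += len(b_true)
    b_true = np.concatenate(kept_true)[: cfg.n_instruments]
    b_obs = np.concatenate(kept_obs)[: cfg.n_instruments]

    n = cfg.n_instruments
    if cfg.pleiotropy == "none":
        alpha = np.zeros(n)
    elif cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.pleio_sd, size=n)
    else:
        alpha = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n)
    b_out = cfg.theta * b_true + alpha + rng.normal(0.0, cfg.se_out, size=n)

    data = pd.DataFrame(
        {
            "SNP": [f"iv{i:04d}" for i in range(n)],
            "beta_exp": b_obs,
            "se_exp": cfg.se_exp,
            "beta_out": b_out,
            "se_out": cfg.se_out,
            "p_exp": two_sided_p(b_obs / cfg.se_exp),
        }
    )
    inst = InstrumentSet(
        exposure_name="exposure", outcome_name="outcome", data=data,
        selection={"p_threshold": cfg.p_threshold, "clump_r2": None,
                   "clump_window_bp": None},
    )
    truth = {
        "theta": cfg.theta,
        "pleiotropy": cfg.pleiotropy,
        "mean_alpha": float(alpha.mean()) if n else 0.0,
        "beta_true": b_true,
        "alpha": alpha,
        "seed": cfg.seed,
    }
    return inst, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")
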