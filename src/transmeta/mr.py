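"""Two-sample Mendelian randomization and summary-based MR (SMR/HEIDI).

Instruments are markers robustly associated with the exposure (p <= 1e-4,
LD-clumped).  Each instrument's Wald ratio beta_out/beta_exp estimates the
causal effect; the estimators differ in how they pool ratios and in their
robustness to horizontal pleiotropy:

- IVW: inverse-variance weighted average (weighted regression through the
  origin); consistent only if all instruments are valid.
- Weighted median: consistent if >=50% of the weight comes from valid
  instruments.
- Mode: consistent if the largest group of instruments with the same ratio
  is valid (kernel-smoothed weighted mode of the ratios).
- Egger: weighted regression with an intercept that absorbs directional
  pleiotropy; the slope is the causal estimate, the intercept a pleiotropy
  test.
- Multivariable IVW: joint weighted regression on several exposures'
  instrument effects, adjusting each causal estimate for the others.

SMR tests whether a molecular trait (e.g. gene expression) mediates a GWAS
signal by combining the top-QTL and GWAS z-scores; HEIDI distinguishes a
single shared causal variant from linkage of distinct variants by testing
heterogeneity of the per-SNP ratio estimates across the LD neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: instrument-selection defaults
INSTRUMENT_P_THRESHOLD = 1e-4
CLUMP_R2_MAX = 0.001
CLUMP_WINDOW_BP = 10_000_000

#: SMR/HEIDI defaults
SMR_P_THRESHOLD = 5e-8
HEIDI_P_THRESHOLD = 1.57e-3
HEIDI_R2_RANGE = (0.05, 0.9)
HEIDI_MAX_SNPS = 20

DEFAULT_BOOTSTRAP_DRAWS = 1000
DEFAULT_BOOTSTRAP_SEED = 20220

_INSTRUMENT_COLS = ("SNP", "beta_exp", "se_exp", "beta_out", "se_out")


class MRError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds (or linear) scale."""

    method: str
    beta: float
    se: float
    p: float
    n_instruments: int
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.959963984540054 * self.se,
                self.beta + 1.959963984540054 * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se, "p": self.p,
            "or": self.or_, "n_instruments": self.n_instruments, **self.extra,
        }


@dataclass(frozen=True)
class SMRResult:
    probe: str
    b_xy: float
    t_smr: float
    p_smr: float
    heidi_p: float | None = None
    n_heidi_snps: int = 0


@dataclass(frozen=True)
class HEIDIResult:
    heidi_p: float | None
    n_snps: int
    reason: str = "ok"


@dataclass
class InstrumentSet:
    """Harmonized exposure-outcome effect pairs for two-sample MR."""

    exposure_name: str
    outcome_name: str
    data: pd.DataFrame
    selection: dict = field(default_factory=lambda: {
        "p_threshold": INSTRUMENT_P_THRESHOLD,
        "clump_r2": CLUMP_R2_MAX,
        "clump_window_bp": CLUMP_WINDOW_BP,
    })

    def __post_init__(self) -> None:
        missing = [c for c in _INSTRUMENT_COLS if c not in self.data.columns]
        if missing:
            raise MRError(f"instrument table missing column(s): {missing}")

    def __len__(self) -> int:
        return self.data.shape[0]

    @classmethod
    def from_tsv(cls, path, exposure_name: str = "exposure",
                 outcome_name: str = "outcome") -> "InstrumentSet":
        """Read the two-sample layout (SNP, beta.exposure, se.exposure, ...)."""
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={
            "beta.exposure": "beta_exp", "se.exposure": "se_exp",
            "beta.outcome": "beta_out", "se.outcome": "se_out",
            "p.exposure": "p_exp",
        })
        return cls(exposure_name=exposure_name, outcome_name=outcome_name, data=df)


def _data(inst) -> pd.DataFrame:
    return inst.data if isinstance(inst, InstrumentSet) else inst


def clump(
    markers: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    r2_max: float = CLUMP_R2_MAX,
    window_bp: int = CLUMP_WINDOW_BP,
    strict: bool = False,
) -> list[str]:
    """Greedy p-value-ordered LD clumping; returns retained marker ids.

    Markers (columns ``SNP CHR BP P``) are visited by ascending p (ties by
    chromosome, position); one is retained iff no already-retained marker on
    the same chromosome within ``window_bp`` has LD r^2 > ``r2_max`` with it.
    ``ld`` is a square signed-r matrix indexed by marker id; a missing pair
    is treated as r^2 = 0 with a warning (or an error in strict mode).
    Without an LD matrix, clumping is distance-only (any same-window marker
    conflicts).
    """
    order = markers.sort_values(["P", "CHR", "BP"], kind="mergesort")
    retained: list[tuple[str, str, int]] = []
    warned = False
    for row in order.itertuples(index=False):
        ok = True
        for snp, chrom, pos in retained:
            if chrom != str(row.CHR) or abs(pos - int(row.BP)) > window_bp:
                continue
            if ld is None:
                ok = False
                break
            try:
                r = float(ld.loc[row.SNP, snp])
            except KeyError:
                if strict:
                    raise MRError(f"LD matrix missing pair ({row.SNP}, {snp})")
                if not warned:
                    logger.warning("LD matrix missing pair(s); treating as r2=0")
                    warned = True
                r = 0.0
            if r * r > r2_max:
                ok = False
                break
        if ok:
            retained.append((row.SNP, str(row.CHR), int(row.BP)))
    return [snp for snp, _, _ in retained]


def _norm_p(z) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _safe_z(beta: float, se: float) -> float:
    if se == 0:
        return np.inf if beta != 0 else 0.0
    return abs(beta / se)


def _wls_se(X: np.ndarray, w: np.ndarray, fit) -> np.ndarray:
    """WLS standard errors with residual scale floored at 1.

    The floor keeps SEs at least at the fixed-effect level implied by the
    per-instrument outcome SEs (multiplicative random-effect inflation only,
    no deflation on under-dispersed data).
    """
    Xw = X * np.sqrt(w)[:, None]
    cov_fixed = np.linalg.inv(Xw.T @ Xw)
    scale = max(1.0, float(fit.scale))
    return np.sqrt(np.diag(cov_fixed) * scale)


def mr_ivw(inst) -> MREstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Fixed-effect weights 1/se_out^2; when the heterogeneity statistic
    Q/(n-1) exceeds 1 the SE is inflated by sqrt(Q/(n-1)).  A single
    instrument reduces to the Wald ratio (flagged).
    """
    d = _data(inst)
    n = d.shape[0]
    if n == 0:
        raise MRError("no instruments")
    be = d["beta_exp"].to_numpy(dtype=float)
    bo = d["beta_out"].to_numpy(dtype=float)
    so = d["se_out"].to_numpy(dtype=float)
    if n == 1:
        beta = float(bo[0] / be[0])
        se = float(abs(so[0] / be[0]))
        return MREstimate("ivw", beta, se, _norm_p(beta / se), 1,
                          extra={"wald_ratio": True})
    w = 1.0 / so**2
    denom = float(np.sum(w * be**2))
    beta = float(np.sum(w * be * bo) / denom)
    se_fixed = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (bo - beta * be) ** 2))
    phi = max(1.0, q / (n - 1))
    se = se_fixed * float(np.sqrt(phi))
    return MREstimate("ivw", beta, se, _norm_p(beta / se), n,
                      extra={"Q": q, "phi": phi})


def _egger_orient(be, bo):
    # Egger requires a consistent exposure orientation: flip rows to beta_exp >= 0
    s = np.where(be < 0, -1.0, 1.0)
    return be * s, bo * s


def mr_egger(inst) -> tuple[MREstimate, MREstimate]:
    """Egger regression: (slope, intercept) estimates with t-based p (df n-2)."""
    d = _data(inst)
    n = d.shape[0]
    if n < 3:
        raise MRError("Egger regression needs >=3 instruments")
    be, bo = _egger_orient(d["beta_exp"].to_numpy(dtype=float),
                           d["beta_out"].to_numpy(dtype=float))
    so = d["se_out"].to_numpy(dtype=float)
    X = sm.add_constant(be)
    w = 1.0 / so**2
    fit = sm.WLS(bo, X, weights=w).fit()
    ses = _wls_se(X, w, fit)
    tp = [2.0 * stats.t.sf(_safe_z(fit.params[i], ses[i]), n - 2) for i in (0, 1)]
    intercept = MREstimate("egger_intercept", float(fit.params[0]), float(ses[0]),
                           float(tp[0]), n)
    slope = MREstimate("egger_slope", float(fit.params[1]), float(ses[1]),
                       float(tp[1]), n)
    return slope, intercept


def _wald_ratios(d: pd.DataFrame):
    be = d["beta_exp"].to_numpy(dtype=float)
    bo = d["beta_out"].to_numpy(dtype=float)
    so = d["se_out"].to_numpy(dtype=float)
    ratios = bo / be
    # first-order ratio SE; weights are its inverse variance
    ratio_se = np.abs(so / be)
    return ratios, ratio_se


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (values need not be sorted)."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def mr_weighted_median(
    inst,
    n_boot: int = DEFAULT_BOOTSTRAP_DRAWS,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> MREstimate:
    """Weighted median of Wald ratios; SE by seeded parametric bootstrap."""
    d = _data(inst)
    n = d.shape[0]
    if n < 3:
        raise MRError("weighted median needs >=3 instruments")
    ratios, ratio_se = _wald_ratios(d)
    w = 1.0 / ratio_se**2
    beta = weighted_median(ratios, w)
    se = _bootstrap_se(d, lambda r, rw: weighted_median(r, rw), n_boot, seed)
    return MREstimate("median", beta, se, _norm_p(beta / se), n,
                      extra={"bootstrap": {"n": n_boot, "seed": seed}})


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    # modified Silverman rule on the ratio distribution
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return factor * 0.9 * s * n ** (-1 / 5) if s > 0 else 0.0


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return np.interp(q, cum, v)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth: float,
                   n_grid: int = 512) -> float:
    if bandwidth <= 0:  # all ratios (essentially) identical
        return float(ratios[int(np.argmax(weights))])
    # search inside the weighted bulk: a near-zero exposure effect produces a
    # wild, near-zero-weight ratio that must not stretch the grid
    qlo, qhi = _weighted_quantile(ratios, weights, [0.01, 0.99])
    lo, hi = qlo - 3 * bandwidth, qhi + 3 * bandwidth
    grid = np.linspace(lo, hi, n_grid)
    cand = np.concatenate([grid, ratios[(ratios >= lo) & (ratios <= hi)]])
    dens = (weights[None, :] * stats.norm.pdf(
        (cand[:, None] - ratios[None, :]) / bandwidth)).sum(axis=1)
    best = float(cand[int(np.argmax(dens))])
    step = (hi - lo) / (n_grid - 1)

    def neg_density(x):
        return -(weights * stats.norm.pdf((x - ratios) / bandwidth)).sum()

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_density, bounds=(best - step, best + step), method="bounded")
    return float(res.x) if -res.fun >= -neg_density(best) else best


def mr_mode(
    inst,
    bandwidth_factor: float = 1.0,
    n_boot: int = DEFAULT_BOOTSTRAP_DRAWS,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> MREstimate:
    """Weighted mode of Wald ratios (normal-kernel density maximum).

    Bandwidth is the modified Silverman rule scaled by ``bandwidth_factor``;
    SE by seeded parametric bootstrap.
    """
    d = _data(inst)
    n = d.shape[0]
    if n < 3:
        raise MRError("mode estimator needs >=3 instruments")
    ratios, ratio_se = _wald_ratios(d)
    w = 1.0 / ratio_se**2
    bw = _mode_bandwidth(ratios, bandwidth_factor)
    beta = _weighted_mode(ratios, w, bw)

    def estimator(r, rw):
        b = _mode_bandwidth(r, bandwidth_factor)
        return _weighted_mode(r, rw, b, n_grid=256)

    se = _bootstrap_se(d, estimator, n_boot, seed)
    return MREstimate("mode", beta, se, _norm_p(beta / se), n,
                      extra={"bandwidth": bw,
                             "bootstrap": {"n": n_boot, "seed": seed}})


def _bootstrap_se(d: pd.DataFrame, estimator, n_boot: int, seed: int) -> float:
    """Parametric bootstrap over instrument sampling noise."""
    rng = np.random.default_rng(seed)
    be = d["beta_exp"].to_numpy(dtype=float)
    se_ = d["se_exp"].to_numpy(dtype=float)
    bo = d["beta_out"].to_numpy(dtype=float)
    so = d["se_out"].to_numpy(dtype=float)
    n = len(be)
    est = np.empty(n_boot)
    for b in range(n_boot):
        be_b = be + rng.standard_normal(n) * se_
        bo_b = bo + rng.standard_normal(n) * so
        be_b = np.where(be_b == 0, np.finfo(float).eps, be_b)
        r = bo_b / be_b
        rw = (be_b / so) ** 2
        est[b] = estimator(r, rw)
    return float(np.std(est, ddof=1))


def mr_multivariable_ivw(
    exposure_betas: pd.DataFrame,
    beta_out,
    se_out,
) -> list[MREstimate]:
    """Multivariable IVW over pooled instruments.

    ``exposure_betas`` has one column per exposure (instrument effects on
    that exposure) over the pooled instrument set; the outcome effects are
    regressed on all exposure columns jointly, without intercept, with
    weights 1/se_out^2.  Each coefficient is that exposure's causal effect
    adjusted for the others.
    """
    X_all = exposure_betas.to_numpy(dtype=float)
    bo = np.asarray(beta_out, dtype=float)
    so = np.asarray(se_out, dtype=float)
    n = X_all.shape[0]
    # an exposure with no instrument signal at all cannot be estimated;
    # drop it from the design and flag it (the others reduce to the fit
    # without it, e.g. univariable IVW for a single remaining exposure)
    active = [i for i in range(X_all.shape[1]) if np.any(X_all[:, i] != 0.0)]
    X = X_all[:, active]
    k = X.shape[1]
    if k == 0:
        raise MRError("no exposure has instrument signal")
    if n <= k:
        raise MRError(f"{n} pooled instruments for {k} exposures: underdetermined")
    w = 1.0 / so**2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.cond(Xw) > 1e8:
        raise MRError("exposure instrument effects are collinear")
    fit = sm.WLS(bo, X, weights=w).fit()
    ses = _wls_se(X, w, fit)
    out = []
    fitted = dict(zip(active, zip(fit.params, ses)))
    for i, name in enumerate(exposure_betas.columns):
        if i in fitted:
            beta, se = (float(v) for v in fitted[i])
            out.append(MREstimate("mv_ivw", beta, se,
                                  float(2.0 * stats.norm.sf(_safe_z(beta, se))), n,
                                  extra={"exposure": str(name)}))
        else:
            out.append(MREstimate("mv_ivw", 0.0, float("nan"), float("nan"), n,
                                  extra={"exposure": str(name),
                                         "no_instrument_signal": True}))
    return out


def smr_test(
    z_qtl: float,
    z_gwas: float,
    beta_qtl: float | None = None,
    beta_gwas: float | None = None,
    probe: str = "probe",
) -> SMRResult:
    """Summary-based MR test at the top QTL marker.

    The mediated-effect estimate is b_xy = beta_gwas / beta_qtl (falling
    back to the z ratio when betas are not supplied, correct up to the SE
    scale) and the test statistic is

        T_SMR = z_gwas^2 z_qtl^2 / (z_gwas^2 + z_qtl^2)

    referred to chi-square with 1 df.  T_SMR is bounded by the weaker of the
    two signals, so a significant SMR requires both a strong QTL and a
    strong GWAS association.
    """
    if z_qtl == 0:
        raise MRError("z_qtl = 0: no instrument strength")
    if beta_qtl is not None and beta_gwas is not None:
        if beta_qtl == 0:
            raise MRError("beta_qtl = 0: no instrument strength")
        b_xy = beta_gwas / beta_qtl
    else:
        b_xy = z_gwas / z_qtl
    zq2 = float(z_qtl) ** 2
    zg2 = float(z_gwas) ** 2
    t = zg2 * zq2 / (zg2 + zq2) if (zg2 + zq2) > 0 else 0.0
    p = float(stats.chi2.sf(t, df=1))
    return SMRResult(probe=probe, b_xy=float(b_xy), t_smr=float(t), p_smr=p)


def heidi_test(
    locus: pd.DataFrame,
    ld: pd.DataFrame,
    r2_range: tuple[float, float] = HEIDI_R2_RANGE,
    max_snps: int = HEIDI_MAX_SNPS,
) -> HEIDIResult:
    """Heterogeneity-in-dependent-instruments test at a QTL locus.

    ``locus`` needs columns ``SNP BETA_QTL SE_QTL BETA_GWAS SE_GWAS``; ``ld``
    is the signed-r matrix over those markers.  The top QTL marker anchors
    the mediated-effect estimate b_xy; neighbours with r^2 to the top marker
    inside ``r2_range`` (capped at ``max_snps``, strongest QTL first)
    contribute deviations d_i = b_xy(i) - b_xy(top).  Under a single shared
    causal variant all d_i are zero in expectation; their covariance follows
    from the LD matrix and per-study SEs by the delta method, and the sum of
    squared standardized deviations is referred to a Satterthwaite-scaled
    chi-square.  A small HEIDI p-value means linkage of distinct causal
    variants rather than mediation.
    """
    d = locus.reset_index(drop=True)
    zq = (d["BETA_QTL"] / d["SE_QTL"]).to_numpy(dtype=float)
    top = int(np.argmax(np.abs(zq)))
    top_snp = d.loc[top, "SNP"]

    r_to_top = np.array([
        float(ld.loc[snp, top_snp]) if snp in ld.index and top_snp in ld.columns else 0.0
        for snp in d["SNP"]
    ])
    r2 = r_to_top**2
    eligible = np.flatnonzero(
        (np.arange(len(d)) != top) & (r2 >= r2_range[0]) & (r2 <= r2_range[1])
    )
    if len(eligible) > max_snps:
        eligible = eligible[np.argsort(-np.abs(zq[eligible]), kind="stable")][:max_snps]
        eligible = np.sort(eligible)
    if len(eligible) < 3:
        return HEIDIResult(None, len(eligible), reason="fewer than 3 eligible SNPs")

    idx = np.concatenate(([top], eligible))
    snps = d.loc[idx, "SNP"].tolist()
    bE = d.loc[idx, "BETA_QTL"].to_numpy(dtype=float)
    sE = d.loc[idx, "SE_QTL"].to_numpy(dtype=float)
    bG = d.loc[idx, "BETA_GWAS"].to_numpy(dtype=float)
    sG = d.loc[idx, "SE_GWAS"].to_numpy(dtype=float)
    R = np.array([[float(ld.loc[si, sj]) for sj in snps] for si in snps])

    bxy = bG / bE
    # delta-method covariance of the per-SNP mediated-effect estimates;
    # the QTL and GWAS samples are independent, so no cross term
    C = (R * np.outer(sG, sG)) / np.outer(bE, bE) \
        + np.outer(bxy, bxy) * (R * np.outer(sE, sE)) / np.outer(bE, bE)

    m = len(idx) - 1
    dvec = bxy[1:] - bxy[0]
    V = C[1:, 1:] - C[1:, [0]] - C[[0], 1:] + C[0, 0]
    vd = np.diag(V)
    if np.any(vd <= 0):
        return HEIDIResult(None, m, reason="non-positive deviation variance")
    zd = dvec / np.sqrt(vd)
    corr = V / np.sqrt(np.outer(vd, vd))
    T = float(np.sum(zd**2))
    mean_T = float(m)
    var_T = float(2.0 * np.sum(corr**2))
    c = var_T / (2.0 * mean_T)
    k = 2.0 * mean_T**2 / var_T
    p = float(stats.chi2.sf(T / c, df=k))
    return HEIDIResult(p, m, reason="ok")


def estimates_to_json(estimates: list[MREstimate]) -> list[dict]:
    return [e.to_dict() for e in estimates]
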