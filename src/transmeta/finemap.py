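"""Approximate-Bayes-factor fine-mapping and single-causal-variant colocalization.

Under a one-causal-variant model with a normal prior N(0, W) on the true
effect, the evidence for association at a marker with estimate (beta, se) is
Wakefield's approximate Bayes factor

    ABF = sqrt(se^2 / (se^2 + W)) * exp(z^2 W / (2 (se^2 + W))),   z = beta/se.

With a flat prior over which marker is causal, posterior inclusion
probabilities are the normalized ABFs, and the 95% credible set is the
smallest prefix of markers, in descending posterior probability, whose
cumulative mass reaches 0.95.

Colocalization of two traits at a locus enumerates five hypotheses: no
association (H0), association with trait 1 only (H1), trait 2 only (H2),
both via distinct causal variants (H3), both via a single shared causal
variant (H4).  Posteriors are accumulated from per-marker ABFs in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: default prior variance of the causal effect (sd 0.2 on the log-odds scale)
DEFAULT_PRIOR_W = 0.04
#: canonical colocalization priors: per-marker probability of being causal
#: for trait 1 only, trait 2 only, or both
DEFAULT_COLOC_PRIORS = (1e-4, 1e-4, 1e-5)


class FinemapError(ValueError):
    pass


@dataclass(frozen=True)
class CredibleSet:
    """Credible set for one locus: table of (SNP, LOG_ABF, PIP, CUM_PIP, IN_SET)."""

    locus_id: str
    source: str
    table: pd.DataFrame
    mass: float
    prior_w: float

    @property
    def size(self) -> int:
        return int(self.table["IN_SET"].sum())

    @property
    def members(self) -> list[str]:
        return list(self.table.loc[self.table["IN_SET"], "SNP"])


@dataclass(frozen=True)
class ColocResult:
    """Posterior over the five colocalization hypotheses at one locus."""

    locus_id: str
    pp: tuple[float, float, float, float, float]
    priors: tuple[float, float, float]
    n_markers: int

    @property
    def pp4(self) -> float:
        return self.pp[4]

    @property
    def best_hypothesis(self) -> str:
        return f"H{int(np.argmax(self.pp))}"

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            **{f"PP{i}": float(v) for i, v in enumerate(self.pp)},
            "priors": {"p1": self.priors[0], "p2": self.priors[1], "p12": self.priors[2]},
            "n_markers": self.n_markers,
        }


def log_abf(beta, se, prior_w: float = DEFAULT_PRIOR_W):
    """Log Wakefield ABF in favor of association; vectorized.

    ``prior_w`` is the prior variance W of the true effect.  As W -> 0 the
    prior collapses to a point mass at zero and the ABF tends to 1.
    """
    if prior_w <= 0:
        raise FinemapError("prior_w must be positive")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise FinemapError("se must be positive")
    v = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + prior_w)) + z2 * prior_w / (2.0 * (v + prior_w))


def wakefield_abf(beta, se, prior_w: float = DEFAULT_PRIOR_W):
    """Wakefield approximate Bayes factor (direct scale); see :func:`log_abf`."""
    return np.exp(log_abf(beta, se, prior_w))


def credible_set(
    locus: pd.DataFrame,
    prior_w: float = DEFAULT_PRIOR_W,
    mass: float = 0.95,
    beta_col: str = "BETA",
    se_col: str = "SE",
    locus_id: str = "locus",
    source: str = "trait",
) -> CredibleSet:
    """Posterior inclusion probabilities and the smallest >=``mass`` set.

    ``locus`` must have columns ``SNP``, ``beta_col`` and ``se_col``.  PIPs
    are normalized ABFs (flat one-causal-variant prior).  Ties in PIP are
    broken by input order (stable sort), so the set is deterministic.
    """
    if locus.empty:
        raise FinemapError("empty locus")
    labf = log_abf(locus[beta_col].to_numpy(), locus[se_col].to_numpy(), prior_w)
    pip = np.exp(labf - logsumexp(labf))
    pip = pip / pip.sum()  # exact renormalization

    order = np.argsort(-pip, kind="stable")
    cum = np.cumsum(pip[order])
    k = int(np.searchsorted(cum, mass) + 1)
    k = min(k, len(pip))
    in_set = np.zeros(len(pip), dtype=bool)
    in_set[order[:k]] = True

    table = pd.DataFrame(
        {
            "SNP": locus["SNP"].to_numpy()[order],
            "LOG_ABF": labf[order],
            "PIP": pip[order],
            "CUM_PIP": cum,
            "IN_SET": in_set[order],
        }
    )
    return CredibleSet(locus_id=locus_id, source=source, table=table, mass=mass, prior_w=prior_w)


def coloc_abf(
    locus: pd.DataFrame,
    priors: tuple[float, float, float] = DEFAULT_COLOC_PRIORS,
    prior_w1: float = DEFAULT_PRIOR_W,
    prior_w2: float = DEFAULT_PRIOR_W,
    locus_id: str = "locus",
) -> ColocResult:
    """Five-hypothesis colocalization posterior from per-marker ABFs.

    ``locus`` must carry harmonized columns ``BETA1 SE1 BETA2 SE2`` (and
    ``SNP``).  All sums over causal configurations are accumulated in log
    space:  H1/H2 sum single-trait ABFs over markers, H4 sums the product of
    both traits' ABFs at the same marker, and H3 sums products at distinct
    markers (computed as the difference of the full product and the H4 term).
    """
    if locus.shape[0] < 2:
        raise FinemapError("colocalization needs at least 2 markers")
    p1, p2, p12 = priors
    l1 = log_abf(locus["BETA1"].to_numpy(), locus["SE1"].to_numpy(), prior_w1)
    l2 = log_abf(locus["BETA2"].to_numpy(), locus["SE2"].to_numpy(), prior_w2)
    if not (np.all(np.isfinite(l1)) and np.all(np.isfinite(l2))):
        bad = locus["SNP"].to_numpy()[~(np.isfinite(l1) & np.isfinite(l2))][0]
        raise FinemapError(f"non-finite ABF at marker {bad}")

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)

    lh0 = 0.0
    lh1 = np.log(p1) + lse1
    lh2 = np.log(p2) + lse2
    # sum_{i != j} ABF1_i ABF2_j = (sum_i ABF1_i)(sum_j ABF2_j) - sum_i ABF1_i ABF2_i
    diff = lse12 - (lse1 + lse2)
    if diff >= 0:
        # all mass on one marker in both traits: the off-diagonal sum underflows
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + lse1 + lse2 + np.log1p(-np.exp(diff))
    lh4 = np.log(p12) + lse12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(
        locus_id=locus_id,
        pp=tuple(float(x) for x in pp),
        priors=(p1, p2, p12),
        n_markers=int(locus.shape[0]),
    )


def credset_shrinkage(
    locus: pd.DataFrame,
    prior_w: float = DEFAULT_PRIOR_W,
    mass: float = 0.95,
    locus_id: str = "locus",
) -> dict[str, int]:
    """Credible-set sizes for trait 1, trait 2 and the TDMA statistic.

    ``locus`` must carry ``BETA1 SE1 BETA2 SE2 BETA_TDMA SE_TDMA`` over the
    same marker set; the TDMA set uses the combined effect and its SE as the
    input pair.  Combining two traits that share a causal variant sharpens
    the posterior, so the TDMA set is typically the smallest.
    """
    sizes = {}
    for label, (b, s) in {
        "size_trait1": ("BETA1", "SE1"),
        "size_trait2": ("BETA2", "SE2"),
        "size_tdma": ("BETA_TDMA", "SE_TDMA"),
    }.items():
        cs = credible_set(locus, prior_w=prior_w, mass=mass, beta_col=b, se_col=s,
                          locus_id=locus_id, source=label)
        sizes[label] = cs.size
    return sizes


def credible_sets_to_frame(sets: list[CredibleSet]) -> pd.DataFrame:
    """Flatten credible sets to a TSV-ready table."""
    frames = []
    for cs in sets:
        t = cs.table.copy()
        t.insert(0, "LOCUS", cs.locus_id)
        t.insert(1, "SOURCE", cs.source)
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["LOCUS", "SOURCE", "SNP", "LOG_ABF", "PIP", "CUM_PIP", "IN_SET"])
    return pd.concat(frames, ignore_index=True)
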