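"""The transmission mean test (TMT).

The TMT treats each heterozygous-parent transmission as a randomized
assignment of the child's phenotype to a control group (allele 0 transmitted)
or a treatment group (allele 1).  Per SNP it computes

* the centered mean-difference estimator
  ``d = (2/N) [ sum_j (Y_j - mu_hat) W1_j - sum_j (Y_j - mu_hat) W0_j ]``
  with ``mu_hat = (sum Y W1 + sum Y W0) / N``, an unbiased estimator of the
  causal transmission parameter delta;
* a sampling-variance estimate built from the within-set unbiased variances of
  the five assignment classes T0, T1, T00, T11, T01 (T01 contributions cancel
  in d and carry no variance term);
* the standardized statistic ``tau = d / sigma_hat`` with a two-sided
  Normal(0,1) p-value, and optionally a phenotype-permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .assignment import AssignmentMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_N = 10

STATUS_OK = "ok"
STATUS_LOW_N = "skipped-low-N"
STATUS_NO_RAND = "skipped-no-randomization"
STATUS_DEGENERATE = "degenerate"


@dataclass
class SetPartition:
    """Index sets of the assignment classes for one SNP.

    Membership is determined solely by (W0j, W1j):
    (1,0) -> T0, (0,1) -> T1, (2,0) -> T00, (0,2) -> T11, (1,1) -> T01.
    """

    t0: np.ndarray
    t1: np.ndarray
    t00: np.ndarray
    t11: np.ndarray
    t01: np.ndarray

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "t0": len(self.t0),
            "t1": len(self.t1),
            "t00": len(self.t00),
            "t11": len(self.t11),
            "t01": len(self.t01),
        }

    def n_from_sizes(self) -> int:
        s = self.sizes
        return s["t0"] + s["t1"] + 2 * (s["t00"] + s["t11"] + s["t01"])


def partition(w0: np.ndarray, w1: np.ndarray) -> SetPartition:
    """Partition trios of one SNP into the assignment classes."""
    w0 = np.asarray(w0)
    w1 = np.asarray(w1)
    return SetPartition(
        t0=np.flatnonzero((w0 == 1) & (w1 == 0)),
        t1=np.flatnonzero((w0 == 0) & (w1 == 1)),
        t00=np.flatnonzero((w0 == 2) & (w1 == 0)),
        t11=np.flatnonzero((w0 == 0) & (w1 == 2)),
        t01=np.flatnonzero((w0 == 1) & (w1 == 1)),
    )


def mu_hat(y, w0, w1) -> float:
    """Population mean estimate over all assignments of one SNP."""
    y, w0, w1 = (np.asarray(a, dtype=float) for a in (y, w0, w1))
    n = (w0 + w1).sum()
    if n == 0:
        raise ValueError("no randomization at this SNP (N = 0)")
    return float((y * (w0 + w1)).sum() / n)


def d_tmt_nc(y, w0, w1) -> float:
    """Uncentered (preliminary) TMT statistic 2/N (sum Y W1 - sum Y W0).

    Unbiased like the centered form but with larger variance; on an
    affected-only binary cohort (every Y = 1) it reduces to the TDT estimand
    2 (N1 - N0) / N, whereas the centered statistic degenerates to zero there
    because the trait carries no contrast.
    """
    y, w0, w1 = (np.asarray(a, dtype=float) for a in (y, w0, w1))
    n = (w0 + w1).sum()
    if n == 0:
        raise ValueError("no randomization at this SNP (N = 0)")
    return float(2.0 / n * ((y * w1).sum() - (y * w0).sum()))


def d_tmt(y, w0, w1, mu: float | None = None) -> float:
    """Centered TMT estimator for one SNP."""
    y, w0, w1 = (np.asarray(a, dtype=float) for a in (y, w0, w1))
    n = (w0 + w1).sum()
    if n == 0:
        raise ValueError("no randomization at this SNP (N = 0)")
    if mu is None:
        mu = mu_hat(y, w0, w1)
    return float(2.0 / n * (((y - mu) * w1).sum() - ((y - mu) * w0).sum()))


def _unbiased_set_var(values: np.ndarray) -> float:
    return float(np.var(values, ddof=1)) if len(values) >= 2 else 0.0


def variance_hat(y, part: SetPartition, n: float) -> float:
    """Sampling-variance estimate of d for one SNP.

    Uses unbiased variances of Y over T0 and T1 and of 2Y over T00 and T11;
    classes with fewer than two members contribute zero (their ddof=1 variance
    is undefined).
    """
    if n <= 0:
        raise ValueError("no randomization at this SNP (N = 0)")
    y = np.asarray(y, dtype=float)
    total = (
        len(part.t0) * _unbiased_set_var(y[part.t0])
        + len(part.t1) * _unbiased_set_var(y[part.t1])
        + len(part.t00) * _unbiased_set_var(2 * y[part.t00])
        + len(part.t11) * _unbiased_set_var(2 * y[part.t11])
    )
    return float(4.0 / n**2 * total)


def _scan(y, w0, w1) -> dict[str, np.ndarray]:
    """Vectorized per-SNP TMT statistics.

    ``y`` is a length-J vector shared across SNPs or an I x J matrix of
    per-SNP phenotype rows (used by permutation and replicate machinery);
    ``w0``/``w1`` are I x J assignment matrices.
    """
    w0 = np.asarray(w0, dtype=float)
    w1 = np.asarray(w1, dtype=float)
    y2 = np.atleast_2d(np.asarray(y, dtype=float))
    wsum = w0 + w1
    wdiff = w1 - w0
    n = wsum.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = (wsum * y2).sum(axis=1) / n
        d = 2.0 / n * ((wdiff * y2).sum(axis=1) - mu * wdiff.sum(axis=1))

    def set_stats(mask):
        cnt = mask.sum(axis=1)
        s1 = (mask * y2).sum(axis=1)
        s2 = (mask * y2**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (s2 - s1**2 / cnt) / (cnt - 1)
        return cnt, np.where(cnt >= 2, np.clip(v, 0.0, None), 0.0)

    n0, v0 = set_stats((w0 == 1) & (w1 == 0))
    n1, v1 = set_stats((w0 == 0) & (w1 == 1))
    n00, v00 = set_stats((w0 == 2) & (w1 == 0))
    n11, v11 = set_stats((w0 == 0) & (w1 == 2))
    n01 = ((w0 == 1) & (w1 == 1)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # variances of 2Y over T00/T11 are 4x the variances of Y
        var = 4.0 / n**2 * (n0 * v0 + n1 * v1 + 4 * n00 * v00 + 4 * n11 * v11)
        tau = np.where(var > 0, d / np.sqrt(var), np.nan)
    p = np.where(np.isfinite(tau), 2.0 * ndtr(-np.abs(tau)), np.nan)
    return {
        "n": n,
        "mu_hat": mu,
        "d_tmt": d,
        "var_hat": var,
        "tau": tau,
        "p_normal": p,
        "n_t0": n0,
        "n_t1": n1,
        "n_t00": n00,
        "n_t11": n11,
        "n_t01": n01,
    }


def _masked_w(assignment: AssignmentMatrix, y: np.ndarray):
    """Zero assignment columns whose phenotype is missing."""
    keep = np.isfinite(y)
    y_f = np.where(keep, y, 0.0)
    w0 = assignment.W0 * keep
    w1 = assignment.W1 * keep
    return y_f, w0, w1


def tmt_test(
    y,
    assignment: AssignmentMatrix,
    snp_meta: pd.DataFrame | None = None,
    min_n: int = DEFAULT_MIN_N,
    permutations: int = 0,
    seed: int | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-SNP TMT scan returning a result table.

    Rows with fewer than ``min_n`` heterozygous parents or a degenerate
    variance estimate are flagged and carry NA statistics.  ``permutations``
    > 0 adds a phenotype-permutation p-value column; ``adjust`` in
    {"bh", "bonferroni"} adds a multiplicity-adjusted column.
    """
    if hasattr(y, "values") and hasattr(y, "kind"):
        if y.kind == "binary":
            obs = y.values[~y.missing]
            if len(obs) and (obs == 1.0).all():
                logger.warning(
                    "all children are affected; the TMT has no phenotype "
                    "contrast -- consider the TDT for affected-only designs"
                )
        y = y.values
    y = np.asarray(y, dtype=float)
    y_f, w0, w1 = _masked_w(assignment, y)
    stats = _scan(y_f, w0, w1)
    n = stats["n"]
    status = np.full(len(n), STATUS_OK, dtype=object)
    status[stats["var_hat"] <= 0] = STATUS_DEGENERATE
    status[n < min_n] = STATUS_LOW_N
    status[n == 0] = STATUS_NO_RAND
    untestable = status != STATUS_OK
    for key in ("mu_hat", "d_tmt", "var_hat", "tau", "p_normal"):
        stats[key] = np.where(untestable, np.nan, stats[key])
    out = pd.DataFrame(stats)
    out["se"] = np.sqrt(out["var_hat"])
    out["n"] = n.astype(int)
    out["status"] = status
    out["n_mendel_excluded"] = assignment.n_mendel_excluded
    out["mendel_flag"] = assignment.mendel_flag()
    if permutations > 0:
        rng = np.random.default_rng(seed)
        p_perm = np.full(len(n), np.nan)
        for i in np.flatnonzero(~untestable):
            p_perm[i] = permutation_p(
                y, assignment, i, permutations, rng=rng
            )
        out["p_perm"] = p_perm
    if adjust in ("bh", "bonferroni"):
        out[f"p_{adjust}"] = _adjust_p(out["p_normal"].to_numpy(), adjust)
    elif adjust not in (None, "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if snp_meta is not None:
        out = pd.concat([snp_meta.reset_index(drop=True), out], axis=1)
    cols_first = [c for c in ("snp_id", "chrom", "pos", "coded_allele") if c in out]
    ordered = cols_first + [
        "n", "mu_hat", "d_tmt", "se", "var_hat", "tau", "p_normal",
    ] + [c for c in ("p_perm", "p_bh", "p_bonferroni") if c in out] + [
        "n_t0", "n_t1", "n_t00", "n_t11", "n_t01",
        "n_mendel_excluded", "mendel_flag", "status",
    ]
    return out[ordered]


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        mapped = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
        out[mask] = multipletests(p[mask], method=mapped)[1]
    return out


def permutation_p(
    y,
    assignment: AssignmentMatrix,
    snp_index: int,
    n_permutations: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Phenotype-permutation p-value for one SNP.

    Permutes Y across trios (genotypes and assignments fixed), recomputing
    tau each time; p = (1 + #{|tau_b| >= |tau_obs|}) / (B + 1).  Ties count
    against the null (>=), and the add-one correction avoids zero p-values.
    A statistic where both d and its variance estimate vanish is treated as
    tau = 0 (no evidence); a nonzero d with zero variance estimate is
    undefined and returns NaN.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    y_f, w0, w1 = _masked_w(assignment, y)
    w0r = w0[snp_index].astype(float)
    w1r = w1[snp_index].astype(float)
    obs = _scan(y_f[None, :] if y_f.ndim == 1 else y_f, w0r[None, :], w1r[None, :])
    tau_obs = _tau_or_zero(obs["d_tmt"], obs["var_hat"])[0]
    if np.isnan(tau_obs):
        return float("nan")
    j = len(y_f)
    order = np.argsort(rng.random((n_permutations, j)), axis=1)
    y_perm = y_f[order]
    b = _scan(y_perm, np.broadcast_to(w0r, y_perm.shape), np.broadcast_to(w1r, y_perm.shape))
    tau_b = _tau_or_zero(b["d_tmt"], b["var_hat"])
    exceed = np.abs(tau_b) >= np.abs(tau_obs)
    return float((1 + np.count_nonzero(exceed)) / (n_permutations + 1))


def _tau_or_zero(d: np.ndarray, var: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(var > 0, d / np.sqrt(var), np.nan)
    return np.where((var <= 0) & (d == 0), 0.0, tau)
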