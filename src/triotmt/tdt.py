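"""The transmission disequilibrium test (TDT) for affected-only trio designs.

For trios recruited through an affected child (binary trait, Y = 1), count
the alleles transmitted by heterozygous parents: N0 copies of allele 0 and N1
of allele 1.  McNemar's statistic ``X^2 = (N1 - N0)^2 / (N1 + N0)`` is chi-
square with one degree of freedom under the null of no causal effect, and
``d = 2 (N1 - N0) / N`` is an unbiased estimator of the same causal parameter
the TMT targets (it equals the TMT estimator when every included child has
Y = 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .assignment import AssignmentMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRANSMISSIONS = 10

STATUS_OK = "ok"
STATUS_LOW_N = "skipped-low-N"
STATUS_UNTESTABLE = "skipped-no-transmissions"


def tdt_counts(assignment: AssignmentMatrix, affected) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP transmitted-allele counts (N0, N1) over affected trios.

    ``affected`` is a boolean/0-1 vector over trios; unaffected trios are
    excluded exactly (their terms are zero).
    """
    a = np.asarray(affected, dtype=float)
    if a.sum() == 0:
        raise ValueError("zero affected trios")
    n0 = assignment.W0.astype(np.int64) @ a.astype(np.int64)
    n1 = assignment.W1.astype(np.int64) @ a.astype(np.int64)
    return n0, n1


def tdt_chisq(n0, n1):
    """McNemar chi-square and its one-degree-of-freedom upper-tail p-value."""
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    total = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(total > 0, (n1 - n0) ** 2 / total, np.nan)
    p = np.where(np.isfinite(stat), chi2.sf(stat, df=1), np.nan)
    if np.ndim(n0) == 0:
        return float(stat), float(p)
    return stat, p


def d_tdt(n0, n1):
    """Unbiased TDT estimand d = 2 (N1 - N0) / (N1 + N0)."""
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    total = n0 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(total > 0, 2.0 * (n1 - n0) / total, np.nan)
    return float(d) if np.ndim(n0) == 0 else d


def tdt_test(
    y,
    assignment: AssignmentMatrix,
    snp_meta: pd.DataFrame | None = None,
    min_transmissions: int = DEFAULT_MIN_TRANSMISSIONS,
) -> pd.DataFrame:
    """Per-SNP TDT scan on the affected children of a binary phenotype.

    Children with Y = 0 (or missing Y) are excluded with a logged count; the
    affected-only design is enforced by construction.  A quantitative
    phenotype is an error.
    """
    if hasattr(y, "values") and hasattr(y, "kind"):
        if y.kind != "binary":
            raise ValueError("the TDT requires a binary phenotype")
        y = y.values
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    if not np.isin(y[obs], (0.0, 1.0)).all():
        raise ValueError("the TDT requires a binary phenotype")
    affected = obs & (y == 1.0)
    n_dropped = int(np.count_nonzero(obs & ~affected))
    if n_dropped:
        logger.info("excluded %d unaffected children from the TDT", n_dropped)
    n0, n1 = tdt_counts(assignment, affected)
    total = n0 + n1
    stat, p = tdt_chisq(n0, n1)
    d = d_tdt(n0, n1)
    status = np.full(len(n0), STATUS_OK, dtype=object)
    status[total < min_transmissions] = STATUS_LOW_N
    status[total == 0] = STATUS_UNTESTABLE
    bad = status != STATUS_OK
    out = pd.DataFrame(
        {
            "n0": n0,
            "n1": n1,
            "n": total,
            "d_tdt": np.where(bad, np.nan, d),
            "chi2": np.where(bad, np.nan, stat),
            "p": np.where(bad, np.nan, p),
            "n_mendel_excluded": assignment.n_mendel_excluded,
            "mendel_flag": assignment.mendel_flag(),
            "status": status,
        }
    )
    if snp_meta is not None:
        out = pd.concat([snp_meta.reset_index(drop=True), out], axis=1)
    return out
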