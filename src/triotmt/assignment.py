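"""Control/treatment assignment from unphased trio genotypes.

Each heterozygous parent constitutes one Mendelian randomization: the child is
assigned once to the control group if that parent transmitted allele 0 and once
to the treatment group if it transmitted allele 1.  Although the transmitted
alleles are not directly observed in unphased data, the per-trio assignment
counts (W0, W1) are fully determined by the genotype triple (Zm, Zp, G) --
including the double-heterozygote child-heterozygote case, where the two
consistent phase resolutions yield the same counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

logger = logging.getLogger(__name__)

#: Per-SNP Mendelian-exclusion rate above which the SNP is flagged in output.
MENDEL_FLAG_RATE = 0.05


def _possible_alleles(z: int) -> tuple[int, ...]:
    """Alleles a parent with genotype ``z`` can transmit."""
    return {0: (0,), 1: (0, 1), 2: (1,)}[z]


def assign_trio(zm: int, zp: int, g: int) -> tuple[int, int, bool]:
    """Assignment counts (w0, w1) for one trio at one SNP.

    Parameters
    ----------
    zm, zp, g
        Maternal, paternal and child genotypes, coded as counts of the coded
        allele in {0, 1, 2}.

    Returns
    -------
    (w0, w1, valid)
        Control and treatment counts, each in {0, 1, 2}, and whether the
        configuration is Mendelian-consistent.  Inconsistent configurations
        return (0, 0, False).
    """
    for v in (zm, zp, g):
        if v not in (0, 1, 2):
            raise ValueError(f"genotype code {v!r} outside {{0,1,2}}")
    pairs = [
        (am, ap)
        for am, ap in product(_possible_alleles(zm), _possible_alleles(zp))
        if am + ap == g
    ]
    if not pairs:
        return 0, 0, False
    # every consistent phase resolution gives the same counts; use the first
    am, ap = pairs[0]
    w0 = (1 - am) * (zm == 1) + (1 - ap) * (zp == 1)
    w1 = am * (zm == 1) + ap * (zp == 1)
    return int(w0), int(w1), True


def _build_lookup() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w0 = np.zeros((3, 3, 3), dtype=np.int8)
    w1 = np.zeros((3, 3, 3), dtype=np.int8)
    ok = np.zeros((3, 3, 3), dtype=bool)
    for zm, zp, g in product(range(3), repeat=3):
        w0[zm, zp, g], w1[zm, zp, g], ok[zm, zp, g] = assign_trio(zm, zp, g)
    return w0, w1, ok


_LUT_W0, _LUT_W1, _LUT_OK = _build_lookup()


@dataclass
class AssignmentMatrix:
    """Per-(SNP, trio) assignment counts for a trio cohort.

    Attributes
    ----------
    W0, W1
        I x J integer matrices of control / treatment counts.  Cells that are
        Mendelian-inconsistent or have a missing genotype carry (0, 0).
    valid
        I x J boolean mask; ``False`` marks excluded cells.
    n_mendel_excluded
        Per-SNP count of Mendelian-inconsistent cells (missing genotypes are
        not counted as inconsistencies).
    """

    W0: np.ndarray
    W1: np.ndarray
    valid: np.ndarray
    n_mendel_excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_mendel_excluded is None:
            self.n_mendel_excluded = np.zeros(self.W0.shape[0], dtype=np.int64)

    @property
    def n_snps(self) -> int:
        return self.W0.shape[0]

    @property
    def n_trios(self) -> int:
        return self.W0.shape[1]

    def mendel_flag(self, rate: float = MENDEL_FLAG_RATE) -> np.ndarray:
        """Boolean per-SNP flag: exclusion rate above ``rate``."""
        j = max(self.n_trios, 1)
        return self.n_mendel_excluded / j > rate


def assign_all(trios) -> AssignmentMatrix:
    """Compute assignment counts for every (SNP, trio) cell.

    ``trios`` is a :class:`triotmt.triodata.TrioGenotypeSet` or any object
    with integer matrices ``G``, ``Zm``, ``Zp`` (missing coded as -1).
    Mendelian-inconsistent cells are excluded per cell (not per trio or per
    SNP) and counted per SNP.
    """
    zm, zp, g = (np.asarray(a) for a in (trios.Zm, trios.Zp, trios.G))
    observed = (zm >= 0) & (zp >= 0) & (g >= 0)
    zm_c, zp_c, g_c = (np.where(observed, a, 0) for a in (zm, zp, g))
    ok = _LUT_OK[zm_c, zp_c, g_c] & observed
    w0 = np.where(ok, _LUT_W0[zm_c, zp_c, g_c], 0).astype(np.int8)
    w1 = np.where(ok, _LUT_W1[zm_c, zp_c, g_c], 0).astype(np.int8)
    n_excl = (observed & ~ok).sum(axis=1).astype(np.int64)
    total = int(n_excl.sum())
    if total:
        logger.warning("excluded %d Mendelian-inconsistent (SNP, trio) cells", total)
    return AssignmentMatrix(W0=w0, W1=w1, valid=ok, n_mendel_excluded=n_excl)


def het_count(assignment: AssignmentMatrix) -> np.ndarray:
    """Per-SNP number of heterozygous parents N over valid cells.

    Equals sum_j (W0j + W1j), since every heterozygous parent contributes
    exactly one assignment; bounded by 2J.
    """
    return (assignment.W0.astype(np.int64) + assignment.W1).sum(axis=1)
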