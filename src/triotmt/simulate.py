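"""Synthetic trio cohorts with population structure and ground-truth oracles.

The generator emulates the study conditions the tests are designed for:

* admixed parental genotypes — per-SNP ancestral frequencies, Balding–Nichols
  subpopulation frequencies at a target fixation index, Dirichlet admixture
  weights shared by the two parents of a trio;
* Mendelian transmission — each parent passes allele 1 with probability
  Z/2, independently per parent and SNP;
* a quantitative trait with per-genotype effects at a causal set plus a
  structure-correlated environmental confounder, a probit-thresholded binary
  trait on the same latent scale, a single-locus design whose confounder
  enters only through homozygous parents, and a two-locus model with
  population LD and meiotic linkage;
* oracle values of the causal parameters (delta for the TMT and TDT, the
  average causal and regression effects) computed from the realized parental
  genotypes, for unbiasedness and calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .triodata import PhenotypeVector, TrioGenotypeSet

__all__ = [
    "SimConfig",
    "ParentPopulation",
    "SimTruth",
    "simulate_parents",
    "transmit",
    "env_confounder",
    "simulate_quantitative",
    "simulate_binary",
    "simulate_confounded",
    "simulate_linked_pair",
    "simulate_cohort",
    "joint_transmission_probs",
    "enumerate_joint_transmission",
    "oracle_delta_tmt",
    "oracle_delta_tdt",
    "oracle_ace",
    "oracle_are",
    "oracle_effects",
    "potential_outcomes",
    "realized_fst",
    "to_vcf",
    "to_fam",
    "write_truth",
]


@dataclass
class SimConfig:
    """Study conditions for the trio simulator.

    Parameters with units: ``fst`` is the target individual-level fixation
    index of the admixed parents; ``h2`` the realized fraction of trait
    variance from the causal set; ``sigma_e`` the nongenetic noise standard
    deviation on the trait scale; ``intercept`` the trait baseline;
    ``beta`` the coefficient of the structure-correlated environment;
    ``effect_ratio`` the dominance shape (alpha2-alpha1)/(alpha1-alpha0),
    1 being additive; ``prevalence`` the binary-trait case fraction;
    ``b``/``s``/``lam`` the single-locus confounded design's genetic effect,
    confounding effect and confounder offset; ``eta_cd``/``theta_cd`` the
    coupling-haplotype probability and recombination fraction of the
    two-locus model.
    """

    n_trios: int = 500
    n_snps: int = 2000
    n_subpops: int = 4
    fst: float = 0.2
    admixture_concentration: float = 0.3
    admixture_weights: np.ndarray | None = None  # J x K override of the Dirichlet draw
    shared_parent_admixture: bool = True
    freq_low: float = 0.05
    freq_high: float = 0.95
    n_causal: int = 100
    effect_ratio: float = 1.0
    h2: float = 0.5
    beta: float = 1.0
    sigma_e: float = 1.0
    intercept: float = 100.0
    env_mix: float = 0.5
    prevalence: float = 0.2
    b: float = 0.0
    s: float = 1.0
    lam: float = 10.0
    eta_cd: float = 0.8
    theta_cd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if self.n_subpops < 2 and self.fst > 0:
            raise ValueError("need at least 2 subpopulations for fst > 0")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        for name in ("eta_cd", "theta_cd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class ParentPopulation:
    """Realized parental genotypes and the structure that generated them."""

    Zm: np.ndarray  # I x J maternal genotypes
    Zp: np.ndarray  # I x J paternal genotypes
    ancestral_freq: np.ndarray  # I
    subpop_freq: np.ndarray  # I x K
    admixture: np.ndarray  # J x K (maternal; == paternal when shared)
    admixture_p: np.ndarray  # J x K paternal
    freq_m: np.ndarray  # I x J individual frequencies, mothers
    freq_p: np.ndarray  # I x J individual frequencies, fathers

    @property
    def n_snps(self) -> int:
        return self.Zm.shape[0]

    @property
    def n_trios(self) -> int:
        return self.Zm.shape[1]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    causal: np.ndarray
    alphas: tuple[float, float, float]
    delta_tmt: np.ndarray  # per SNP; 0 outside the causal set
    env: np.ndarray  # confounder E per child
    eps: np.ndarray
    h2_realized: float | None = None
    kind: str = "quantitative"
    threshold: float | None = None
    prevalence_realized: float | None = None
    latent: np.ndarray | None = None
    delta_tdt: np.ndarray | None = None
    eta: np.ndarray | None = None
    Am: np.ndarray | None = None
    Ap: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parents and transmission


def _balding_nichols_F(config: SimConfig) -> float:
    """Inbreeding parameter giving the target individual-level fixation index.

    The individual-level index equals F_BN * E[sum_k q_k^2]; for symmetric
    Dirichlet(a) admixture weights E[sum_k q_k^2] = (a+1)/(K a + 1).
    """
    if config.fst == 0:
        return 0.0
    a = config.admixture_concentration
    k = config.n_subpops
    return min(0.99, config.fst * (k * a + 1) / (a + 1))


def simulate_parents(config: SimConfig, rng: np.random.Generator) -> ParentPopulation:
    """Draw structured parental genotypes for ``config.n_trios`` trios."""
    i, j, k = config.n_snps, config.n_trios, config.n_subpops
    p_anc = rng.uniform(config.freq_low, config.freq_high, size=i)
    f = _balding_nichols_F(config)
    if f > 0:
        shape_a = p_anc * (1 - f) / f
        shape_b = (1 - p_anc) * (1 - f) / f
        subpop = rng.beta(shape_a[:, None], shape_b[:, None], size=(i, k))
    else:
        subpop = np.repeat(p_anc[:, None], k, axis=1)
    if config.admixture_weights is not None:
        q_m = np.asarray(config.admixture_weights, dtype=float)
        if q_m.shape != (j, k):
            raise ValueError("admixture_weights must have shape (n_trios, n_subpops)")
        q_p = q_m
    else:
        conc = np.full(k, config.admixture_concentration)
        q_m = rng.dirichlet(conc, size=j)
        q_p = q_m if config.shared_parent_admixture else rng.dirichlet(conc, size=j)
    freq_m = subpop @ q_m.T
    freq_p = subpop @ q_p.T if q_p is not q_m else freq_m
    zm = rng.binomial(2, freq_m).astype(np.int8)
    zp = rng.binomial(2, freq_p).astype(np.int8)
    return ParentPopulation(
        Zm=zm, Zp=zp, ancestral_freq=p_anc, subpop_freq=subpop,
        admixture=q_m, admixture_p=q_p, freq_m=freq_m, freq_p=freq_p,
    )


def transmit(zm, zp, rng: np.random.Generator):
    """Mendelian transmission: A = 0, Bernoulli(1/2), 1 for Z = 0, 1, 2."""
    zm = np.asarray(zm)
    zp = np.asarray(zp)
    am = (zm == 2) + ((zm == 1) & (rng.random(zm.shape) < 0.5))
    ap = (zp == 2) + ((zp == 1) & (rng.random(zp.shape) < 0.5))
    am = am.astype(np.int8)
    ap = ap.astype(np.int8)
    return am, ap, (am + ap).astype(np.int8)


def realized_fst(pop: ParentPopulation) -> float:
    """Wright-style fixation index of the parents' individual frequencies.

    Ratio of sums over SNPs of the mean squared deviation of individual
    frequencies from the (known) ancestral frequency to the ancestral
    heterozygosity term p(1-p).
    """
    pi = np.concatenate([pop.freq_m, pop.freq_p], axis=1)
    p = pop.ancestral_freq
    num = ((pi - p[:, None]) ** 2).mean(axis=1).sum()
    den = (p * (1 - p)).sum()
    return float(num / den)


# ---------------------------------------------------------------------------
# traits


def env_confounder(pop: ParentPopulation, config: SimConfig, rng: np.random.Generator):
    """Structure-correlated nongenetic confounder E per child.

    A standardized linear combination of the trio's admixture weights mixed
    with independent Normal noise; ``env_mix`` is the fraction of variance
    from the structure component.
    """
    w = rng.normal(size=pop.admixture.shape[1])
    raw = pop.admixture @ w
    sd = raw.std()
    struct = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    noise = rng.normal(size=len(raw))
    m = config.env_mix
    return np.sqrt(m) * struct + np.sqrt(1 - m) * noise


def _genetic_values(g_causal: np.ndarray, alphas) -> np.ndarray:
    lut = np.asarray(alphas, dtype=float)
    return lut[g_causal].sum(axis=0)


def _calibrated_alphas(g_causal, other, config: SimConfig):
    """Scale the per-genotype effects so the realized heritability is h2.

    ``other`` is the realized nongenetic component (beta E + eps).  Because
    the causal genotypes and the structured environment are correlated, the
    scale c solves the quadratic
    (1 - h2) Vg c^2 - 2 h2 C c - h2 V_other = 0
    with Vg the unscaled genetic variance and C its covariance with
    ``other``, so that Var(genetic) / Var(total) equals h2 on the cohort.
    """
    base = np.array([0.0, 1.0, 1.0 + config.effect_ratio])
    if config.h2 == 0 or g_causal.shape[0] == 0:
        if config.h2 > 0:
            raise ValueError("empty causal set with h2 > 0")
        return (0.0, 0.0, 0.0)
    genetic = _genetic_values(g_causal, base)
    var_g = genetic.var()
    if var_g == 0:
        raise ValueError("no genetic variance in causal set")
    var_other = other.var()
    cov = np.cov(genetic, other)[0, 1]
    h2 = config.h2
    a = (1 - h2) * var_g
    c = (h2 * cov + np.sqrt(h2**2 * cov**2 + a * h2 * var_other)) / a
    return tuple(float(c * v) for v in base)


def _latent_trait(g, causal, pop, config, rng, alphas=None):
    env = env_confounder(pop, config, rng)
    g_causal = np.asarray(g)[causal]
    eps = rng.normal(0.0, config.sigma_e, size=g.shape[1])
    if alphas is None:
        alphas = _calibrated_alphas(g_causal, config.beta * env + eps, config)
    genetic = _genetic_values(g_causal, alphas)
    y = config.intercept + genetic + config.beta * env + eps
    var_tot = y.var()
    h2_real = float(genetic.var() / var_tot) if var_tot > 0 else 0.0
    return y, env, eps, alphas, h2_real


def simulate_quantitative(
    g, pop: ParentPopulation, config: SimConfig, rng: np.random.Generator,
    causal=None, alphas=None,
):
    """Quantitative trait with causal-set genetic values and confounded E.

    Returns (Y, SimTruth); the truth carries the scaled per-genotype effects
    and the oracle TMT parameter per SNP (zero outside the causal set).
    """
    causal = _default_causal(g.shape[0], config, causal, rng)
    y, env, eps, alphas, h2_real = _latent_trait(g, causal, pop, config, rng, alphas)
    delta = oracle_delta_tmt(pop, alphas, causal)
    truth = SimTruth(
        causal=causal, alphas=alphas, delta_tmt=delta, env=env, eps=eps,
        h2_realized=h2_real, kind="quantitative",
    )
    return y, truth


def simulate_binary(
    g, pop: ParentPopulation, config: SimConfig, rng: np.random.Generator,
    causal=None, alphas=None,
):
    """Probit-thresholded binary trait at the configured prevalence.

    The latent scale is the quantitative model; the threshold is the
    empirical (1 - prevalence) quantile of the latent values, so the realized
    prevalence matches the configuration exactly (up to rounding).
    """
    causal = _default_causal(g.shape[0], config, causal, rng)
    latent, env, eps, alphas, h2_real = _latent_trait(g, causal, pop, config, rng, alphas)
    thr = float(np.quantile(latent, 1.0 - config.prevalence))
    y = (latent > thr).astype(float)
    if y.min() == y.max():
        raise ValueError("degenerate binary threshold: all children share one label")
    delta = oracle_delta_tmt(pop, alphas, causal)
    truth = SimTruth(
        causal=causal, alphas=alphas, delta_tmt=delta, env=env, eps=eps,
        h2_realized=h2_real, kind="binary", threshold=thr,
        prevalence_realized=float(y.mean()), latent=latent,
    )
    return y, truth


def _default_causal(n_snps, config, causal, rng):
    if causal is not None:
        return np.asarray(causal, dtype=int)
    n = min(config.n_causal, n_snps)
    return np.sort(rng.choice(n_snps, size=n, replace=False))


def simulate_confounded(zm, zp, g, config: SimConfig, rng: np.random.Generator):
    """Single-locus trait with a homozygous-parent confounder.

    Y = intercept + b G + s kappa + eps with
    kappa = (Zm + Zp - lam) * I(Zm != 1 and Zp != 1): the confounder tracks
    the parental genotypes but vanishes whenever either parent is
    heterozygous, so the transmission randomization is unconfounded while a
    naive per-locus regression of Y on G is biased.
    """
    zm = np.asarray(zm, dtype=float)
    zp = np.asarray(zp, dtype=float)
    g = np.asarray(g, dtype=float)
    kappa = (zm + zp - config.lam) * ((zm != 1) & (zp != 1))
    eps = rng.normal(0.0, config.sigma_e, size=g.shape)
    y = config.intercept + config.b * g + config.s * kappa + eps
    truth = {"kappa": kappa, "delta_tmt": config.b, "b": config.b, "s": config.s}
    return y, truth


# ---------------------------------------------------------------------------
# two-locus LD + meiotic linkage


def _haplotype_freqs(eta: float, pc: float = 0.5, pd_: float = 0.5) -> np.ndarray:
    """Haplotype frequencies (h00, h01, h10, h11) whose double-heterozygote
    coupling probability equals ``eta``."""
    base = np.array([(1 - pc) * (1 - pd_), (1 - pc) * pd_, pc * (1 - pd_), pc * pd_])

    def coupling(dv):
        h00, h01, h10, h11 = base + np.array([dv, -dv, -dv, dv])
        return h00 * h11 / (h00 * h11 + h01 * h10) - eta

    lo = -min(base[0], base[3]) + 1e-9
    hi = min(base[1], base[2]) - 1e-9
    if eta <= 0:
        d = lo
    elif eta >= 1:
        d = hi
    else:
        d = brentq(coupling, lo, hi)
    return base + np.array([d, -d, -d, d])


_HAP_ALLELES = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])  # (allele_c, allele_d)


def simulate_linked_pair(config: SimConfig, rng: np.random.Generator):
    """Two-locus trio cohort with LD (eta_cd) and meiotic linkage (theta_cd).

    Parents carry diplotypes drawn from haplotype frequencies whose
    double-heterozygote coupling probability is ``eta_cd``; each parent
    transmits one haplotype with recombination probability ``theta_cd``
    between the causal locus c and the linked marker d.  The trait depends on
    locus c only: Y = intercept + b Gc + eps.

    Returns (TrioGenotypeSet with rows [c, d], Y, truth dict).
    """
    j = config.n_trios
    hfreq = _haplotype_freqs(config.eta_cd)
    # two haplotypes per parent, two parents per trio
    haps = rng.choice(4, size=(2, 2, j), p=hfreq)  # (parent, hap slot, trio)
    alleles = _HAP_ALLELES[haps]  # (...,2) -> allele_c, allele_d
    z_c = alleles[..., 0].sum(axis=1).astype(np.int8)  # (parent, trio)
    z_d = alleles[..., 1].sum(axis=1).astype(np.int8)
    pick = rng.integers(0, 2, size=(2, j))  # haplotype transmitting locus c
    recomb = rng.random((2, j)) < config.theta_cd
    idx_p = np.arange(2)[:, None]
    idx_j = np.arange(j)[None, :]
    a_c = alleles[idx_p, pick, idx_j, 0]
    a_d = alleles[idx_p, np.where(recomb, 1 - pick, pick), idx_j, 1]
    g_c = a_c.sum(axis=0).astype(np.int8)
    g_d = a_d.sum(axis=0).astype(np.int8)
    b = config.b if config.b != 0 else 1.0
    eps = rng.normal(0.0, config.sigma_e, size=j)
    y = config.intercept + b * g_c + eps
    meta = pd.DataFrame(
        {
            "snp_id": ["locus_c", "locus_d"],
            "chrom": ["1", "1"],
            "pos": [1000, 2000],
            "coded_allele": ["A", "A"],
            "other_allele": ["G", "G"],
        }
    )
    trios = _trio_id_frame(j)
    ts = TrioGenotypeSet(
        G=np.vstack([g_c, g_d]),
        Zm=np.vstack([z_c[0], z_d[0]]),
        Zp=np.vstack([z_c[1], z_d[1]]),
        snp_meta=meta,
        trio_ids=trios,
    )
    truth = {
        "b": b,
        "delta_c": b,
        "Am": np.vstack([a_c[0], a_d[0]]),
        "Ap": np.vstack([a_c[1], a_d[1]]),
        "haplotype_freqs": hfreq,
    }
    return ts, y, truth


def joint_transmission_probs(eta: float, theta: float) -> dict:
    """Closed-form joint transmission law P(Ad, Ac | double heterozygote)."""
    same = 0.5 * eta * (1 - theta) + 0.5 * (1 - eta) * theta
    diff = 0.5 * (1 - eta) * (1 - theta) + 0.5 * eta * theta
    return {(1, 1): same, (0, 0): same, (0, 1): diff, (1, 0): diff}


def enumerate_joint_transmission(eta: float, theta: float) -> dict:
    """Joint transmission law by enumerating the gamete mechanism.

    Walks every (diplotype configuration, transmitting haplotype,
    recombination outcome) path of a double-heterozygous parent with its
    probability; independent of the closed form.
    """
    out = {(a, b): 0.0 for a in (0, 1) for b in (0, 1)}
    configs = [
        (eta, ((0, 0), (1, 1))),  # coupling: (allele_c, allele_d) pairs
        (1 - eta, ((0, 1), (1, 0))),  # repulsion
    ]
    for p_cfg, haps in configs:
        for i in (0, 1):  # haplotype transmitting locus c
            for recomb, p_rec in ((False, 1 - theta), (True, theta)):
                ac = haps[i][0]
                ad = haps[1 - i][1] if recomb else haps[i][1]
                out[(ad, ac)] += p_cfg * 0.5 * p_rec
    return out


# ---------------------------------------------------------------------------
# oracles


def oracle_delta_tmt(pop: ParentPopulation, alphas, causal) -> np.ndarray:
    """Oracle TMT parameter per SNP from the realized parental genotypes.

    Each heterozygous parent slot contributes the expected within-parent
    potential-outcome difference, which by the transmission law E[A|Z] = Z/2
    is (a1-a0) (1 - z_other/2) + (a2-a1) z_other/2 with z_other the other
    parent's genotype; delta is the mean over the N heterozygous slots.
    This is the finite-cohort conditional estimand the transmission-mean
    estimator targets, and it converges to the per-side population
    definition as the cohort grows.  Zero at every SNP outside the causal
    set; NaN where a causal SNP has no heterozygous parents.
    """
    a0, a1, a2 = alphas
    delta = np.zeros(pop.n_snps)
    for i in np.asarray(causal, dtype=int):
        zm = pop.Zm[i].astype(float)
        zp = pop.Zp[i].astype(float)
        hm = zm == 1
        hp = zp == 1
        n_slots = hm.sum() + hp.sum()
        if n_slots == 0:
            delta[i] = np.nan
            continue

        def slot_diff(z_other):
            p1 = z_other / 2.0
            return (a1 - a0) * (1 - p1) + (a2 - a1) * p1

        delta[i] = (slot_diff(zp[hm]).sum() + slot_diff(zm[hp]).sum()) / n_slots
    return delta


def oracle_ace(alphas, zm_row, zp_row) -> tuple[float, float]:
    """Average causal effects of the maternal and paternal transmitted allele.

    ACE(Am -> Y) = (a1-a0) P(Ap=0) + (a2-a1) P(Ap=1) and symmetrically, with
    P(A=1) = E[Z]/2 estimated from the realized parental genotypes.
    """
    a0, a1, a2 = alphas
    p_ap1 = float(np.mean(np.asarray(zp_row, dtype=float) / 2))
    p_am1 = float(np.mean(np.asarray(zm_row, dtype=float) / 2))
    ace_m = (a1 - a0) * (1 - p_ap1) + (a2 - a1) * p_ap1
    ace_p = (a1 - a0) * (1 - p_am1) + (a2 - a1) * p_am1
    return ace_m, ace_p


def oracle_are(y, a) -> float:
    """Average regression effect E[Y | A=1] - E[Y | A=0] (empirical)."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    if (a == 1).sum() == 0 or (a == 0).sum() == 0:
        return float("nan")
    return float(y[a == 1].mean() - y[a == 0].mean())


def oracle_effects(pop: ParentPopulation, alphas, snp: int, y=None, am=None, ap=None) -> dict:
    """Causal and regression oracles for one SNP of a simulated cohort."""
    out = {}
    ace_m, ace_p = oracle_ace(alphas, pop.Zm[snp], pop.Zp[snp])
    out["ace_m"], out["ace_p"] = ace_m, ace_p
    out["delta_tmt"] = oracle_delta_tmt(pop, alphas, [snp])[snp]
    if y is not None and am is not None:
        out["are_m"] = oracle_are(y, am)
    if y is not None and ap is not None:
        out["are_p"] = oracle_are(y, ap)
    return out


def potential_outcomes(y, g_row, ap_row, alphas):
    """Per-child maternal-side potential outcomes for one causal SNP.

    With gamma the non-focal remainder of the trait, gamma = Y - alpha[G],
    Ym(0) = a0 I(Ap=0) + a1 I(Ap=1) + gamma and
    Ym(1) = a1 I(Ap=0) + a2 I(Ap=1) + gamma.
    """
    a0, a1, a2 = alphas
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_row, dtype=int)
    ap = np.asarray(ap_row, dtype=int)
    gamma = y - np.asarray(alphas, dtype=float)[g]
    y0 = a0 * (ap == 0) + a1 * (ap == 1) + gamma
    y1 = a1 * (ap == 0) + a2 * (ap == 1) + gamma
    return y0, y1


def oracle_delta_tdt(
    pop: ParentPopulation,
    config: SimConfig,
    causal,
    alphas,
    n_reps: int = 400,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Brute-force TDT parameter per causal SNP at fixed parental genotypes.

    Replays the full binary-trait mechanism (transmission, latent trait,
    prevalence threshold) ``n_reps`` times and pools the conditional
    expectations of the TDT parameter definition:
    delta = eta * (E[2 Am - 1 | Y=1, Zm=1] + E[2 Ap - 1 | Y=1, Zp=1])
    with eta = P(Y=1 | Z=1) over heterozygous parent slots.
    """
    rng = np.random.default_rng() if rng is None else rng
    causal = np.asarray(causal, dtype=int)
    zm_c = pop.Zm[causal]
    zp_c = pop.Zp[causal]
    het_m = zm_c == 1
    het_p = zp_c == 1
    n_het_slots = het_m.sum(axis=1) + het_p.sum(axis=1)
    aff_het = np.zeros(len(causal))
    sum_m = np.zeros(len(causal))
    cnt_m = np.zeros(len(causal))
    sum_p = np.zeros(len(causal))
    cnt_p = np.zeros(len(causal))
    for _ in range(n_reps):
        am, ap, g = transmit(zm_c, zp_c, rng)
        latent, *_ = _latent_trait(
            g, np.arange(len(causal)), pop, config, rng, alphas=alphas
        )
        thr = np.quantile(latent, 1.0 - config.prevalence)
        y = latent > thr
        aff_het += (het_m & y).sum(axis=1) + (het_p & y).sum(axis=1)
        sel_m = het_m & y
        sel_p = het_p & y
        sum_m += ((2 * am - 1) * sel_m).sum(axis=1)
        cnt_m += sel_m.sum(axis=1)
        sum_p += ((2 * ap - 1) * sel_p).sum(axis=1)
        cnt_p += sel_p.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = aff_het / (n_het_slots * n_reps)
        e_m = np.where(cnt_m > 0, sum_m / cnt_m, np.nan)
        e_p = np.where(cnt_p > 0, sum_p / cnt_p, np.nan)
    delta = np.zeros(pop.n_snps)
    delta[causal] = eta * (e_m + e_p)
    return delta


# ---------------------------------------------------------------------------
# cohort assembly and writers


def _trio_id_frame(j: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "child": [f"trio{t + 1:05d}_c" for t in range(j)],
            "mother": [f"trio{t + 1:05d}_m" for t in range(j)],
            "father": [f"trio{t + 1:05d}_f" for t in range(j)],
        }
    )


def _snp_meta_frame(i: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [f"snp{s + 1:06d}" for s in range(i)],
            "chrom": "1",
            "pos": [1000 * (s + 1) for s in range(i)],
            "coded_allele": "A",
            "other_allele": "G",
        }
    )


def simulate_cohort(
    config: SimConfig,
    seed: int | None = None,
    binary: bool = False,
    rng: np.random.Generator | None = None,
):
    """Full pipeline: parents, transmission, trait; returns
    (TrioGenotypeSet, PhenotypeVector, SimTruth)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    pop = simulate_parents(config, rng)
    am, ap, g = transmit(pop.Zm, pop.Zp, rng)
    if binary:
        y, truth = simulate_binary(g, pop, config, rng)
        kind = "binary"
    else:
        y, truth = simulate_quantitative(g, pop, config, rng)
        kind = "quantitative"
    truth.Am, truth.Ap = am, ap
    truth.extras["population"] = pop
    ts = TrioGenotypeSet(
        G=g, Zm=pop.Zm, Zp=pop.Zp,
        snp_meta=_snp_meta_frame(config.n_snps),
        trio_ids=_trio_id_frame(config.n_trios),
    )
    pheno = PhenotypeVector(values=y, kind=kind)
    return ts, pheno, truth


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def to_vcf(trios: TrioGenotypeSet, path) -> None:
    """Write the cohort as an unphased VCFv4.2 text file.

    Sample order is mothers, fathers, children in trio order; REF is the
    other allele and ALT the coded allele, so ALT-allele counts round-trip.
    """
    samples, columns = [], []
    for role, mat in (("mother", trios.Zm), ("father", trios.Zp), ("child", trios.G)):
        samples += list(trios.trio_ids[role])
        columns.append(mat)
    geno = np.hstack(columns)
    contigs = list(dict.fromkeys(trios.snp_meta["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=triotmt-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i in range(trios.n_snps):
            m = trios.snp_meta.iloc[i]
            gts = "\t".join(_GT[int(v)] for v in geno[i])
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.snp_id}\t{m.other_allele}\t"
                f"{m.coded_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def to_fam(trios: TrioGenotypeSet, path) -> None:
    """Write a PLINK-style .fam defining the trios."""
    with open(path, "w") as fh:
        for t, r in trios.trio_ids.iterrows():
            fid = f"F{t + 1:05d}"
            fh.write(f"{fid} {r.father} 0 0 1 -9\n")
            fh.write(f"{fid} {r.mother} 0 0 2 -9\n")
            fh.write(f"{fid} {r.child} {r.father} {r.mother} 0 -9\n")


def write_truth(truth: SimTruth, snp_meta: pd.DataFrame, path) -> None:
    """Per-SNP ground-truth TSV (causal flag, effects, oracle delta)."""
    i = len(snp_meta)
    causal_flag = np.zeros(i, dtype=int)
    causal_flag[truth.causal] = 1
    df = pd.DataFrame(
        {
            "snp_id": snp_meta["snp_id"],
            "causal": causal_flag,
            "alpha0": np.where(causal_flag, truth.alphas[0], 0.0),
            "alpha1": np.where(causal_flag, truth.alphas[1], 0.0),
            "alpha2": np.where(causal_flag, truth.alphas[2], 0.0),
            "delta_tmt": truth.delta_tmt,
        }
    )
    if truth.delta_tdt is not None:
        df["delta_tdt"] = truth.delta_tdt
    with open(path, "w") as fh:
        fh.write(f"##kind={truth.kind}\n")
        if truth.h2_realized is not None:
            fh.write(f"##h2_realized={truth.h2_realized:.6f}\n")
        if truth.threshold is not None:
            fh.write(f"##threshold={truth.threshold:.6f}\n")
            fh.write(f"##prevalence={truth.prevalence_realized:.6f}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
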