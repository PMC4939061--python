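"""Nuclear-family simulator for discordant sib pairs at two SNPs.

Founder haplotypes over the two SNPs are drawn from a four-frequency
haplotype model parameterised by the two minor allele frequencies and the
LD measure r^2 (r^2 = 0 gives linkage equilibrium, where the four
frequencies factorize). Each family draws two parents (two haplotypes
each), produces two offspring by random transmission of one intact
haplotype per parent, and assigns affection independently per offspring
from the logistic penetrance

    P(Affected | X) = expit(rho + l1*X1 + l2*X2 + l3*X1*X2)

where X codes the genotype at each disease SNP under an additive (minor
allele count), dominant, or recessive model. Families are retained if and
only if exactly one of the two offspring is affected (a discordant sib
pair); rejection sampling repeats until the requested number of DSPs is
collected. The intercept rho is calibrated so the population prevalence
E[P(Affected | X)] over the founder genotype distribution matches a
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .genio import DspCohort

DISEASE_MODELS = ("additive", "dominant", "recessive")


@dataclass
class TwoSnpHaplotypeModel:
    """Haplotype frequencies over two SNPs with given MAFs and r^2.

    ``freqs`` holds (h_AB, h_Ab, h_aB, h_ab) with uppercase = minor allele,
    first letter SNP1, second SNP2.
    """

    maf1: float
    maf2: float
    r2: float
    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be non-negative and sum to 1")
        p1 = f[0] + f[1]
        p2 = f[0] + f[2]
        if abs(p1 - self.maf1) > 1e-12 or abs(p2 - self.maf2) > 1e-12:
            raise ValueError("haplotype frequencies inconsistent with stated MAFs")


def haplotype_freqs(maf1: float, maf2: float, r2: float = 0.0) -> TwoSnpHaplotypeModel:
    """Build the two-SNP haplotype model for given MAFs and r^2 (D > 0).

    D = sqrt(r2 * p1(1-p1) * p2(1-p2)); raises if D exceeds the Lewontin
    bound min(p1(1-p2), (1-p1)p2), reporting the maximum feasible r^2.
    """
    if not (0 < maf1 <= 0.5 and 0 < maf2 <= 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    if not (0 <= r2 < 1):
        raise ValueError("r2 must lie in [0, 1)")
    q1, q2 = 1 - maf1, 1 - maf2
    d = np.sqrt(r2 * maf1 * q1 * maf2 * q2)
    d_max = min(maf1 * q2, q1 * maf2)
    if d > d_max + 1e-12:
        r2_max = d_max**2 / (maf1 * q1 * maf2 * q2)
        raise ValueError(
            f"r2={r2} infeasible for MAFs ({maf1}, {maf2}); max feasible r2 is {r2_max:.6g}"
        )
    freqs = np.array(
        [maf1 * maf2 + d, maf1 * q2 - d, q1 * maf2 - d, q1 * q2 + d]
    )
    freqs = np.clip(freqs, 0.0, None)
    return TwoSnpHaplotypeModel(maf1, maf2, r2, freqs)


@dataclass
class PenetranceModel:
    """Logistic penetrance with intercept rho and effects (l1, l2, l3)."""

    rho: float
    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: float = 0.0
    disease_model: str = "additive"

    def __post_init__(self):
        if self.disease_model not in DISEASE_MODELS:
            raise ValueError(f"disease_model must be one of {DISEASE_MODELS}")

    def code(self, dose: np.ndarray) -> np.ndarray:
        """Genotype coding X from minor-allele dose (0, 1, 2)."""
        if self.disease_model == "additive":
            return dose
        if self.disease_model == "dominant":
            return (dose >= 1).astype(dose.dtype)
        return (dose == 2).astype(dose.dtype)

    def affection_prob(self, dose1: np.ndarray, dose2: np.ndarray) -> np.ndarray:
        x1 = self.code(dose1)
        x2 = self.code(dose2)
        return expit(self.rho + self.lambda1 * x1 + self.lambda2 * x2 + self.lambda3 * x1 * x2)


@dataclass
class SimDesign:
    """Full specification of one simulated-cohort scenario."""

    n_dsp: int
    haplotypes: TwoSnpHaplotypeModel
    penetrance: PenetranceModel
    prevalence: float | None = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.n_dsp < 1:
            raise ValueError("n_dsp must be >= 1")
        if self.prevalence is not None and not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")


def genotype_pair_distribution(model: TwoSnpHaplotypeModel) -> np.ndarray:
    """3x3 joint distribution of minor-allele doses (rows SNP1, cols SNP2)
    for a random union of two haplotypes (HWE at the haplotype level)."""
    h = model.freqs
    dose1 = np.array([1, 1, 0, 0])  # minor-allele dose per haplotype
    dose2 = np.array([1, 0, 1, 0])
    dist = np.zeros((3, 3))
    for i in range(4):
        for j in range(4):
            dist[dose1[i] + dose1[j], dose2[i] + dose2[j]] += h[i] * h[j]
    return dist


def calibrate_rho(
    penetrance: PenetranceModel,
    haplotypes: TwoSnpHaplotypeModel,
    target_prevalence: float,
) -> float:
    """Solve E[P(Affected | X)] = target over the founder genotype
    distribution; the expectation is strictly increasing in rho."""
    if not (0 < target_prevalence < 1):
        raise ValueError("target prevalence must lie in (0, 1)")
    dist = genotype_pair_distribution(haplotypes)
    d1, d2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    x1 = penetrance.code(d1)
    x2 = penetrance.code(d2)
    eta = (
        penetrance.lambda1 * x1
        + penetrance.lambda2 * x2
        + penetrance.lambda3 * x1 * x2
    )

    def prevalence(rho):
        return float(np.sum(dist * expit(rho + eta))) - target_prevalence

    return brentq(prevalence, -60.0, 60.0, xtol=1e-12)


def _resolved_penetrance(design: SimDesign) -> PenetranceModel:
    if design.prevalence is None:
        return design.penetrance
    rho = calibrate_rho(design.penetrance, design.haplotypes, design.prevalence)
    return replace(design.penetrance, rho=rho)


def _simulate_pair_doses(
    design: SimDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate until n_dsp discordant families; return minor-allele doses
    (aff_snp1, aff_snp2, unaff_snp1, unaff_snp2)."""
    pen = _resolved_penetrance(design)
    h_cum = np.cumsum(design.haplotypes.freqs)
    h_cum[-1] = 1.0
    need = design.n_dsp
    out = [[], [], [], []]
    got = 0
    drawn = 0
    p_acc = 0.1  # refined after the first batch
    while got < need:
        n = int(min(max((need - got) / p_acc * 1.25, 2000), 4_000_000))
        # 4 parental haplotypes per family: parent1 x2, parent2 x2
        haps = np.searchsorted(h_cum, rng.random((n, 4)))
        # each child receives one haplotype from each parent
        pick = rng.integers(0, 2, size=(n, 4))  # (c1<-p1, c1<-p2, c2<-p1, c2<-p2)
        rows = np.arange(n)
        c1_h1 = haps[rows, pick[:, 0]]
        c1_h2 = haps[rows, 2 + pick[:, 1]]
        c2_h1 = haps[rows, pick[:, 2]]
        c2_h2 = haps[rows, 2 + pick[:, 3]]

        def dose(hap_a, hap_b, snp):
            if snp == 1:
                return (hap_a < 2).astype(np.int8) + (hap_b < 2).astype(np.int8)
            return (hap_a % 2 == 0).astype(np.int8) + (hap_b % 2 == 0).astype(np.int8)

        d1_c1, d2_c1 = dose(c1_h1, c1_h2, 1), dose(c1_h1, c1_h2, 2)
        d1_c2, d2_c2 = dose(c2_h1, c2_h2, 1), dose(c2_h1, c2_h2, 2)
        aff1 = rng.random(n) < pen.affection_prob(d1_c1, d2_c1)
        aff2 = rng.random(n) < pen.affection_prob(d1_c2, d2_c2)
        disc = aff1 != aff2
        drawn += n
        idx = np.flatnonzero(disc)
        if idx.size:
            a_first = aff1[idx]
            out[0].append(np.where(a_first, d1_c1[idx], d1_c2[idx]))
            out[1].append(np.where(a_first, d2_c1[idx], d2_c2[idx]))
            out[2].append(np.where(a_first, d1_c2[idx], d1_c1[idx]))
            out[3].append(np.where(a_first, d2_c2[idx], d2_c1[idx]))
            got += idx.size
        p_acc = max(got / drawn, 1e-6)
        if drawn >= 2_000_000 and got / drawn < 1e-5:
            raise RuntimeError(
                f"DSP acceptance rate {got/drawn:.2e} below 1e-5; check the design"
            )
    cat = [np.concatenate(c)[:need] for c in out]
    return cat[0], cat[1], cat[2], cat[3]


def simulate_dsp_cohort(design: SimDesign, rng: np.random.Generator | None = None) -> DspCohort:
    """Simulate a cohort of ``design.n_dsp`` discordant sib pairs.

    Fully reproducible for a fixed ``design.seed`` (or a supplied
    generator). Genotype codes follow the reader convention: 1 = homozygous
    minor, 2 = heterozygous, 3 = homozygous major.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    a1, a2, u1, u2 = _simulate_pair_doses(design, rng)
    aff = np.stack([3 - a1, 3 - a2], axis=1).astype(np.int8)
    unaff = np.stack([3 - u1, 3 - u2], axis=1).astype(np.int8)
    fams = [f"F{i+1}" for i in range(design.n_dsp)]
    return DspCohort(aff, unaff, fams)


_ALLELES = {1: ("A", "A"), 2: ("A", "G"), 3: ("G", "G")}


def write_ped_map(cohort: DspCohort, prefix: str, *, ld: bool = False) -> None:
    """Write a cohort as PLINK text PED/MAP.

    Each family is written as two sibs with dummy untyped parents. Minor
    allele is 'A', major 'G' (the reader's lexicographic tie-break keeps
    'A' minor even at 50/50 counts). The two SNPs go on one chromosome when
    ``ld`` is true, otherwise on chromosomes 1 and 2.
    """
    m = cohort.n_snps
    with open(f"{prefix}.map", "w") as fh:
        for j in range(m):
            if ld:
                chrom, pos = "1", 1000 + j * 500
            else:
                chrom, pos = str(j + 1), 1000
            fh.write(f"{chrom}\tsnp{j+1}\t0\t{pos}\n")
    with open(f"{prefix}.ped", "w") as fh:
        for s in range(cohort.k):
            fam = cohort.family_ids[s]
            fh.write(f"{fam}\tP1\t0\t0\t1\t0" + "\t0 0" * m + "\n")
            fh.write(f"{fam}\tP2\t0\t0\t2\t0" + "\t0 0" * m + "\n")
            for iid, row, pheno in (("S1", cohort.aff[s], 2), ("S2", cohort.unaff[s], 1)):
                geno = "\t".join(" ".join(_ALLELES[int(g)]) if g else "0 0" for g in row)
                fh.write(f"{fam}\t{iid}\tP1\tP2\t0\t{pheno}\t{geno}\n")
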