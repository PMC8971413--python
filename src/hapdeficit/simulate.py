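"""Forward simulation of an AI-breeding cattle population with an embedded
recessive risk haplotype.

The generator emulates the data structure that a missing-homozygosity scan
assumes: a pedigree dominated by a few heavily used sires, phased SNP
genotypes transmitted by gene-drop with Haldane (no-interference)
recombination, a recessive haplotype whose homozygotes are removed before
genotyping with a configurable penetrance, and EBV-like pseudo-phenotypes
with declared reliabilities.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``SimConfig.seed``; identical configs give bit-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Trait abbreviation vocabulary (fertility, birth and survival traits).
TRAIT_CODES = (
    "NRh", "NRc", "IFLh", "IFLc", "DFS",
    "CEd", "SBd", "BWd", "GLd", "MBd",
    "CEm", "SBm", "BWm", "GLm", "MBm",
    "P1", "P2h", "P2b",
)

_FOUNDER_BIRTH_YEAR = 2009
_BP_SPACING = 20_000  # 50 SNP ~ 1 Mb, emulating 114k-array density


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic breeding population.

    ``risk_hap_freq`` is the target founder frequency of the risk
    haplotype; ``penetrance`` is the probability that a homozygous-risk
    conceptus is removed before genotyping (1.0 = embryonic lethal).
    ``sire_usage_decay`` is the geometric ratio of per-sire usage weights
    (1.0 = uniform usage, i.e. random mating among the selected sires).
    """

    n_founders: int = 200
    n_generations: int = 4
    n_sires_per_gen: int = 8
    offspring_per_dam: int = 2
    n_snps: int = 500
    n_chromosomes: int = 2
    map_length_cM_per_chr: float = 5.0
    risk_hap_freq: float = 0.05
    penetrance: float = 1.0
    trait_h2: float = 0.25
    hap_trait_effect: float = 0.0
    female_genotyping_rate: float = 0.5
    risk_window_size: int = 50
    sire_usage_decay: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.risk_hap_freq < 1.0):
            raise ValueError("risk_hap_freq must lie in (0, 1)")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must lie in [0, 1]")
        if not (0.0 < self.trait_h2 < 1.0):
            raise ValueError("trait_h2 must lie in (0, 1)")
        if not (0.0 <= self.female_genotyping_rate <= 1.0):
            raise ValueError("female_genotyping_rate must lie in [0, 1]")
        if not (0.0 < self.sire_usage_decay <= 1.0):
            raise ValueError("sire_usage_decay must lie in (0, 1]")
        for name in ("n_founders", "n_generations", "n_sires_per_gen",
                     "offspring_per_dam", "n_snps", "n_chromosomes",
                     "risk_window_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_snps // self.n_chromosomes < self.risk_window_size:
            raise ValueError(
                "each chromosome must carry at least risk_window_size SNPs")
        # A scan over this population is vacuous when no carrier x carrier
        # mating is even expected; fail loudly instead of returning noise.
        n_conceptions = (self.n_founders / 2) * self.offspring_per_dam \
            * self.n_generations
        carrier_freq = 2 * self.risk_hap_freq * (1 - self.risk_hap_freq)
        expected_carrier_matings = n_conceptions * carrier_freq ** 2
        if expected_carrier_matings < 1.0:
            raise ValueError(
                "config expects fewer than one carrier x carrier mating "
                f"({expected_carrier_matings:.2f}); increase population size, "
                "generations or risk_hap_freq — a deficit scan on such a "
                "population would be vacuous")


@dataclass
class PhasedGenotypeMatrix:
    """Phased biallelic genotypes: two 0/1 haplotypes per animal."""

    animal_ids: list[str]
    snps: pd.DataFrame  # columns: snp_id, chrom, pos, cM
    haplotypes: np.ndarray  # (n_animals, 2, n_snps) uint8
    phase_known: bool = True

    def __post_init__(self) -> None:
        n, two, s = self.haplotypes.shape
        if two != 2 or n != len(self.animal_ids) or s != len(self.snps):
            raise ValueError("haplotype array shape inconsistent with ids/snps")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("SNP positions must strictly increase within a chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage matrix, shape (n_animals, n_snps)."""
        return self.haplotypes.sum(axis=1)

    def row(self, animal_id: str) -> int:
        try:
            return self.animal_ids.index(animal_id)
        except ValueError:
            raise KeyError(f"animal {animal_id!r} not genotyped") from None


@dataclass
class TruthRecord:
    """Ground truth of the embedded risk haplotype and trait effects."""

    chrom: str
    snp_start_index: int  # global 0-based index into the SNP table, inclusive
    snp_end_index: int    # exclusive
    bp_start: int
    bp_end: int
    pattern: np.ndarray   # 0/1 allele string of the risk haplotype
    copies: pd.Series     # risk-allele copies per animal (all animals, living)
    config: SimConfig
    trait_effects: dict = field(default_factory=dict)

    @property
    def carriers(self) -> pd.Index:
        return self.copies.index[self.copies >= 1]


def resolve_mgs(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Attach the maternal-grandsire column, resolved through the dam."""
    dam_sire = pedigree.set_index("animal_id")["sire_id"]
    mgs = pedigree["dam_id"].map(dam_sire).fillna("0")
    out = pedigree.copy()
    out["mgs_id"] = mgs
    return out


def _gamete(rng: np.random.Generator, haps: np.ndarray,
            chrom_slices: list[tuple[int, int]], cm: np.ndarray,
            map_length: float) -> np.ndarray:
    """One meiosis: Haldane crossovers, uniform placement, random start phase."""
    gam = np.empty(haps.shape[1], dtype=np.uint8)
    for a, b in chrom_slices:
        k = rng.poisson(map_length / 100.0)
        phase0 = rng.integers(2)
        if k == 0:
            gam[a:b] = haps[phase0, a:b]
            continue
        points = np.sort(rng.uniform(0.0, map_length, size=k))
        crossings = np.searchsorted(points, cm[a:b], side="right")
        phase = (phase0 + crossings) % 2
        gam[a:b] = haps[phase, np.arange(a, b)]
    return gam


def _build_snp_table(config: SimConfig) -> tuple[pd.DataFrame, list[tuple[int, int]], np.ndarray]:
    per_chr = config.n_snps // config.n_chromosomes
    rows = []
    slices = []
    cm_all = []
    idx = 0
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        n = per_chr + (config.n_snps % config.n_chromosomes
                       if c == config.n_chromosomes - 1 else 0)
        pos = (np.arange(n) + 1) * _BP_SPACING
        cm = np.linspace(0.0, config.map_length_cM_per_chr, n)
        for j in range(n):
            rows.append((f"snp_{chrom}_{j + 1}", chrom, int(pos[j]), float(cm[j])))
        slices.append((idx, idx + n))
        cm_all.append(cm)
        idx += n
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "cM"])
    return snps, slices, np.concatenate(cm_all)


def _risk_copies(hap: np.ndarray, start: int, end: int, pattern: np.ndarray) -> int:
    return int((hap[0, start:end] == pattern).all()) + \
        int((hap[1, start:end] == pattern).all())


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, PhasedGenotypeMatrix,
                                                    pd.DataFrame, TruthRecord]:
    """Gene-drop simulation of the breeding population.

    Returns ``(pedigree, genotypes, traits, truth)``. The pedigree covers
    every living animal; the genotype matrix only the genotyped subset
    (all males, females at ``female_genotyping_rate``). Homozygous-risk
    conceptuses are silently removed with probability ``penetrance``
    before entering either table — the scan must infer the loss from the
    homozygote deficit alone.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    snps, chrom_slices, cm = _build_snp_table(config)
    S = len(snps)

    # Founders: per-SNP allele frequencies Uniform(0.05, 0.95), mirroring a
    # MAF>0.01 quality filter while avoiding monomorphic windows.
    freqs = rng.uniform(0.05, 0.95, size=S)
    n0 = config.n_founders
    founder_haps = (rng.uniform(size=(n0, 2, S)) < freqs).astype(np.uint8)

    # Risk haplotype: fixed allele pattern over a contiguous window in the
    # middle of chromosome 1, seeded one copy per selected founder.
    a, b = chrom_slices[0]
    w = config.risk_window_size
    start = a + (b - a - w) // 2
    end = start + w
    pattern = rng.integers(0, 2, size=w, dtype=np.uint8)
    n_seed = max(1, round(2 * n0 * config.risk_hap_freq))
    n_seed = min(n_seed, n0)
    seeded = rng.choice(n0, size=n_seed, replace=False)
    which_hap = rng.integers(2, size=n_seed)
    founder_haps[seeded, which_hap, start:end] = pattern

    sex = np.array(["M"] * (n0 // 2) + ["F"] * (n0 - n0 // 2))
    rng.shuffle(sex)

    hap_list: list[np.ndarray] = [founder_haps[i] for i in range(n0)]
    ped_rows: list[tuple] = [
        (f"AN{i + 1:06d}", "0", "0", sex[i], _FOUNDER_BIRTH_YEAR, 0)
        for i in range(n0)]
    next_id = n0 + 1

    prev_males = [i for i in range(n0) if sex[i] == "M"]
    prev_females = [i for i in range(n0) if sex[i] == "F"]

    for g in range(1, config.n_generations + 1):
        if not prev_males or not prev_females:
            logger.warning("generation %d has no available parents; stopping", g)
            break
        n_sires = min(config.n_sires_per_gen, len(prev_males))
        sires = rng.choice(prev_males, size=n_sires, replace=False)
        weights = config.sire_usage_decay ** np.arange(n_sires)
        weights = weights / weights.sum()
        new_males: list[int] = []
        new_females: list[int] = []
        for dam in prev_females:
            sire = int(rng.choice(sires, p=weights))
            for _ in range(config.offspring_per_dam):
                pat = _gamete(rng, hap_list[sire], chrom_slices, cm,
                              config.map_length_cM_per_chr)
                mat = _gamete(rng, hap_list[dam], chrom_slices, cm,
                              config.map_length_cM_per_chr)
                child = np.stack([pat, mat])
                if _risk_copies(child, start, end, pattern) == 2 \
                        and rng.uniform() < config.penetrance:
                    continue  # conceptus lost before genotyping, no record
                child_sex = "M" if rng.uniform() < 0.5 else "F"
                idx = len(hap_list)
                hap_list.append(child)
                ped_rows.append((f"AN{next_id:06d}",
                                 f"AN{sire + 1:06d}", f"AN{dam + 1:06d}",
                                 child_sex, _FOUNDER_BIRTH_YEAR + g, 0))
                next_id += 1
                (new_males if child_sex == "M" else new_females).append(idx)
        prev_males, prev_females = new_males, new_females

    pedigree = pd.DataFrame(
        ped_rows,
        columns=["animal_id", "sire_id", "dam_id", "sex", "birth_year", "genotyped"])
    n_animals = len(pedigree)

    genotyped = np.where(
        pedigree["sex"].to_numpy() == "M", True,
        rng.uniform(size=n_animals) < config.female_genotyping_rate)
    pedigree["genotyped"] = genotyped.astype(int)
    pedigree = resolve_mgs(pedigree)

    geno_idx = np.flatnonzero(genotyped)
    haps = np.stack([hap_list[i] for i in geno_idx])
    genotypes = PhasedGenotypeMatrix(
        animal_ids=[pedigree["animal_id"].iloc[i] for i in geno_idx],
        snps=snps, haplotypes=haps, phase_known=True)

    copies = pd.Series(
        [_risk_copies(hap_list[i], start, end, pattern) for i in range(n_animals)],
        index=pedigree["animal_id"], name="risk_copies")
    truth = TruthRecord(
        chrom=snps["chrom"].iloc[start],
        snp_start_index=start, snp_end_index=end,
        bp_start=int(snps["pos"].iloc[start]), bp_end=int(snps["pos"].iloc[end - 1]),
        pattern=pattern, copies=copies, config=config,
        trait_effects={"NRh": config.hap_trait_effect})

    traits = simulate_trait_ebvs(
        pedigree, genotypes, truth, h2=config.trait_h2,
        hap_effect=config.hap_trait_effect,
        seed=int(rng.integers(2 ** 31)))
    return pedigree, genotypes, traits, truth


def simulate_trait_ebvs(pedigree: pd.DataFrame, genotypes: PhasedGenotypeMatrix,
                        truth: TruthRecord, h2: float, hap_effect: float,
                        seed: int, trait_code: str = "NRh",
                        reliability: float | tuple[float, float] = (0.4, 0.95),
                        ) -> pd.DataFrame:
    """EBV-like pseudo-phenotypes for the genotyped animals.

    The true breeding value is a genomic infinitesimal polygenic term of
    variance ``h2`` (trait variance 1) plus ``hap_effect`` per risk-allele
    copy. The EBV is a shrunken predictor ``r*TBV + noise`` whose squared
    correlation with the TBV equals the declared reliability ``r``; the
    corresponding deregressed pseudo-phenotype (EBV/r) is an unbiased,
    noisy version of the TBV.

    ``reliability`` may be a constant or a ``(low, high)`` uniform range.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    if trait_code not in TRAIT_CODES:
        raise ValueError(f"unknown trait code {trait_code!r}")
    rng = np.random.default_rng(seed)

    dos = genotypes.dosage().astype(float)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    Z = dos[:, poly] - 2 * p[poly]
    u = rng.normal(0.0, np.sqrt(h2 / denom), size=poly.sum())
    tbv = Z @ u
    tbv += hap_effect * truth.copies.loc[genotypes.animal_ids].to_numpy()

    n = genotypes.n_animals
    if np.isscalar(reliability):
        rel = np.full(n, float(reliability))
    else:
        lo, hi = reliability
        rel = rng.uniform(lo, hi, size=n)
    if np.any((rel <= 0) | (rel > 1)):
        raise ValueError("reliabilities must lie in (0, 1]")
    ebv = rel * tbv + np.sqrt(rel * (1 - rel) * h2) * rng.normal(size=n)

    out = pd.DataFrame({
        "animal_id": genotypes.animal_ids,
        "trait": trait_code,
        "ebv": ebv,
        "reliability": rel,
    })
    out.attrs["tbv"] = pd.Series(tbv, index=pd.Index(genotypes.animal_ids,
                                                     name="animal_id"))
    return out


def simulate_candidate_variants(genotypes: PhasedGenotypeMatrix, truth: TruthRecord,
                                n_background: int = 30, seed: int = 0,
                                flank_bp: int = 2_000_000) -> list:
    """Candidate variants in the risk region: one causal + background noise.

    The causal variant rides on every copy of the risk haplotype and
    nowhere else (its dosage equals the truth diplotype). Background
    variants segregate independently at low frequency. All animals are
    labelled Holstein; consequence classes and FILTER status are set so
    the causal variant passes the array-design rules.
    """
    from .prioritize import CandidateVariant

    rng = np.random.default_rng(seed)
    n = genotypes.n_animals
    chrom = truth.chrom
    lo = max(1, truth.bp_start - flank_bp)
    hi = truth.bp_end + flank_bp
    breeds = np.array(["Holstein"] * n)

    causal_dos = truth.copies.loc[genotypes.animal_ids].to_numpy(float)
    causal_pos = (truth.bp_start + truth.bp_end) // 2 + 7  # off-grid position
    variants = [CandidateVariant(
        chrom=chrom, pos=int(causal_pos), ref="C", alt="T",
        consequence="missense", hard_filter_pass=True,
        dosages=causal_dos, breeds=breeds, gene="CAUSAL1",
        description="SNV (missense)", coding_change="c.1A>G")]

    positions = rng.choice(np.arange(lo, hi), size=n_background, replace=False)
    consequences = rng.choice(
        ["missense", "splice", "inframe_deletion", "nonsense", "other"],
        size=n_background)
    for k in range(n_background):
        f = rng.uniform(0.005, 0.05)
        dos = rng.binomial(2, f, size=n).astype(float)
        miss = rng.uniform(size=n) < 0.02
        dos[miss] = np.nan
        variants.append(CandidateVariant(
            chrom=chrom, pos=int(positions[k]), ref="A", alt="G",
            consequence=str(consequences[k]),
            hard_filter_pass=bool(rng.uniform() < 0.9),
            dosages=dos, breeds=breeds, gene=f"BG{k + 1}",
            description="SNV", coding_change="."))
    variants.sort(key=lambda v: v.pos)
    return variants


def power_scan_config(seed: int = 0, penetrance: float = 1.0,
                      hap_trait_effect: float = 0.0) -> SimConfig:
    """The reference study scenario: a common fully lethal haplotype in a
    population sized so its truth window carries >=20 expected homozygotes
    under both the trio and the pgp design.

    The founder frequency budgets for purging: full lethality erodes the
    allele deterministically (q -> q/(1+q) per generation), and the pgp
    design has no generation-1 records (founder dams carry no recorded
    sire), so the late generations must still carry enough carrier sires.
    """
    return SimConfig(
        n_founders=600, n_generations=4, n_sires_per_gen=25,
        offspring_per_dam=2, n_snps=400, n_chromosomes=2,
        map_length_cM_per_chr=4.0, risk_hap_freq=0.3,
        penetrance=penetrance, trait_h2=0.25,
        hap_trait_effect=hap_trait_effect,
        female_genotyping_rate=0.9, sire_usage_decay=0.9, seed=seed)


def null_calibration_config(seed: int = 0) -> SimConfig:
    """Null scenario (no lethality) for test-calibration studies.

    Same population as :func:`power_scan_config` but with 2000 SNPs spread
    over forty 50-SNP chromosomes, so each chromosome carries exactly one
    scan window and the tested window alleles are mutually (nearly)
    independent. Overlapping step-1 windows of one haplotype lineage share
    their deficit, so a single chance event would otherwise dominate any
    pooled false-positive count; one window per chromosome removes that
    correlation and makes binomial sampling theory apply to the pooled
    rate.
    """
    return SimConfig(
        n_founders=500, n_generations=4, n_sires_per_gen=15,
        offspring_per_dam=2, n_snps=2000, n_chromosomes=40,
        map_length_cM_per_chr=0.5, risk_hap_freq=0.25,
        penetrance=0.0, trait_h2=0.25, hap_trait_effect=0.0,
        female_genotyping_rate=0.8, sire_usage_decay=0.8, seed=seed)
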