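"""Missing-homozygosity scan over sliding-window haplotype alleles.

For each window allele the scan computes, per offspring in the chosen
design, the Mendelian probability of being homozygous for the allele:

* trio design (sire, dam and offspring genotyped):
  ``pi = t(sire_copies) * t(dam_copies)`` with t(0)=0, t(1)=1/2, t(2)=1;
* pgp design (sire, maternal grandsire and offspring genotyped):
  ``pi = t(sire_copies) * (t(mgs_copies)/2 + q/2)`` — the granddam's
  untracked haplotype is assigned the population allele frequency ``q``.

The number of homozygotes among n offspring is then a Poisson-binomial
variable; the exact one-sided deficit p-value is its lower tail
``P(X <= observed)``, evaluated by dynamic-programming convolution.
P-values are corrected across all tested alleles by Benjamini–Yekutieli,
and significant overlapping windows are merged into named regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simulate import PhasedGenotypeMatrix, resolve_mgs
from .windows import (HaplotypeAllele, WindowSpec, enumerate_windows,
                      window_alleles, window_allele_codes, _window_matrix)

logger = logging.getLogger(__name__)

_TRANSMIT = np.array([0.0, 0.5, 1.0])


@dataclass(frozen=True)
class MatingRecord:
    """One offspring with the parental copy numbers that determine its
    homozygosity probability."""

    offspring_id: str
    design: str  # 'trio' or 'pgp'
    sire_copies: int
    dam_or_mgs_copies: int
    pi: float


@dataclass
class DeficitResult:
    allele: HaplotypeAllele
    design: str
    n_offspring_considered: int
    observed_hom: int
    expected_hom: float
    deficiency_pct: int | None
    allele_freq_pct: float
    p_raw: float
    p_adj_by: float = math.nan


@dataclass
class HaplotypeRegion:
    name: str
    chrom: str
    bp_start: int
    bp_end: int
    best_window: DeficitResult
    supporting_windows: int
    designs_detected: frozenset = field(default_factory=frozenset)


def per_offspring_prob(design: str, sire_copies: int,
                       dam_or_mgs_copies: int, q: float) -> float:
    """Probability that one offspring is homozygous for the target allele."""
    if sire_copies not in (0, 1, 2) or dam_or_mgs_copies not in (0, 1, 2):
        raise ValueError("copy numbers must be 0, 1 or 2")
    if not (0.0 <= q < 1.0):
        raise ValueError("q must lie in [0, 1)")
    t_sire = _TRANSMIT[sire_copies]
    if design == "trio":
        return float(t_sire * _TRANSMIT[dam_or_mgs_copies])
    if design == "pgp":
        return float(t_sire * (_TRANSMIT[dam_or_mgs_copies] / 2.0 + q / 2.0))
    raise ValueError(f"unknown design {design!r}")


def expected_homozygotes(matings) -> float:
    """Sum of per-offspring homozygosity probabilities."""
    pis = _as_pis(matings)
    if pis.size == 0:
        logger.warning("expected_homozygotes called with no matings")
        return 0.0
    return float(pis.sum())


def _as_pis(matings) -> np.ndarray:
    if len(matings) and isinstance(matings[0], MatingRecord):
        pis = np.array([m.pi for m in matings], dtype=float)
    else:
        pis = np.asarray(matings, dtype=float)
    if pis.size and (np.any(pis < 0) or np.any(pis > 1)):
        raise ValueError("homozygosity probabilities must lie in [0, 1]")
    return pis


def exact_deficit_test(matings, observed_hom: int) -> float:
    """One-sided lower tail P(X <= observed_hom) of the Poisson-binomial
    count of homozygotes, by truncated DP convolution.

    Offspring with pi = 0 cannot contribute a homozygote and drop out of
    the convolution; the DP only tracks counts up to ``observed_hom``,
    so the cost is O(n * observed_hom).
    """
    pis = _as_pis(matings)
    if observed_hom < 0:
        raise ValueError("observed_hom must be >= 0")
    if observed_hom > pis.size:
        raise ValueError("observed_hom exceeds the number of offspring")
    pis = pis[pis > 0]
    if observed_hom >= pis.size:
        return 1.0
    k = observed_hom
    if k == 0:
        return float(np.prod(1.0 - pis))
    dp = np.zeros(k + 1)
    dp[0] = 1.0
    for p in pis:
        dp[1:] = dp[1:] * (1.0 - p) + dp[:-1] * p
        dp[0] *= 1.0 - p
    return float(dp.sum())


def by_adjust(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def deficiency_pct(observed: int, expected: float) -> int:
    """Percent deficiency round(100 * (1 - observed/expected)), half-up."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    return int(math.floor(100.0 * (1.0 - observed / expected) + 0.5))


def build_mating_index(genotypes: PhasedGenotypeMatrix, pedigree: pd.DataFrame,
                       design: str) -> pd.DataFrame:
    """Rows (offspring, sire, dam-or-mgs) as row indices into the genotype
    matrix, for every genotyped offspring whose design links are genotyped.

    Each animal is counted as offspring exactly once even if it also
    appears as a parent of later records.
    """
    if design not in ("trio", "pgp"):
        raise ValueError(f"unknown design {design!r}")
    ped = pedigree
    if "mgs_id" not in ped.columns:
        ped = resolve_mgs(ped)
    row_of = {aid: i for i, aid in enumerate(genotypes.animal_ids)}
    other_col = "dam_id" if design == "trio" else "mgs_id"
    rows = []
    for aid, sire, other in ped[["animal_id", "sire_id", other_col]].itertuples(index=False):
        if aid in row_of and sire in row_of and other in row_of:
            rows.append((row_of[aid], row_of[sire], row_of[other]))
    if not rows:
        if design == "trio":
            raise ValueError(
                "no complete genotyped trios (are any dams genotyped?); "
                "consider the pgp design instead")
        raise ValueError("no complete genotyped sire/maternal-grandsire records")
    return pd.DataFrame(rows, columns=["off", "sire", "other"])


def scan(genotypes: PhasedGenotypeMatrix, pedigree: pd.DataFrame, design: str,
         window_size: int = 50, step: int = 1, min_expected: float = 10.0,
         alpha: float = 0.05, maf_floor: float = 0.01,
         use_pgp_q_term: bool = True,
         include_non_deficit: bool = False) -> list[DeficitResult]:
    """Scan every window allele for a homozygote deficit.

    An allele is *tested* when its frequency is >= ``maf_floor`` and its
    expected homozygote count is >= ``min_expected``; Benjamini–Yekutieli
    adjustment runs across all tested alleles, and a DeficitResult is
    emitted for tested alleles with observed < expected, sorted by
    adjusted then raw p-value. ``include_non_deficit=True`` returns every
    tested allele instead (for calibration studies); the deficiency
    percentage is None where observed >= expected.
    """
    mat_idx = build_mating_index(genotypes, pedigree, design)
    off = mat_idx["off"].to_numpy()
    sire = mat_idx["sire"].to_numpy()
    other = mat_idx["other"].to_numpy()
    n_off = len(off)

    tested: list[DeficitResult] = []
    for window in enumerate_windows(genotypes, window_size, step):
        hapmat = _window_matrix(genotypes, window)
        first, inverse, counts = window_allele_codes(hapmat)
        inverse = inverse.reshape(-1, 2)
        total = hapmat.shape[0]
        for k in np.argsort(-counts, kind="stable"):
            freq = counts[k] / total
            if freq < maf_floor:
                break  # alleles are visited in descending frequency
            copies = (inverse == k).sum(axis=1)
            q = freq if use_pgp_q_term else 0.0
            sc = copies[sire]
            oc = copies[other]
            if design == "trio":
                pis = _TRANSMIT[sc] * _TRANSMIT[oc]
            else:
                pis = _TRANSMIT[sc] * (_TRANSMIT[oc] / 2.0 + q / 2.0)
            expected = float(pis.sum())
            if expected < min_expected:
                continue
            observed = int((copies[off] == 2).sum())
            p_raw = exact_deficit_test(pis, observed)
            tested.append(DeficitResult(
                allele=HaplotypeAllele(window=window,
                                       allele_string="".join(map(str, hapmat[first[k]])),
                                       frequency=freq, count=int(counts[k])),
                design=design,
                n_offspring_considered=n_off,
                observed_hom=observed,
                expected_hom=expected,
                deficiency_pct=(deficiency_pct(observed, expected)
                                if observed < expected else None),
                allele_freq_pct=100.0 * freq,
                p_raw=p_raw))
    if not tested:
        logger.warning("no window allele reached min_expected=%g", min_expected)
        return []
    adj = by_adjust([r.p_raw for r in tested])
    for r, a in zip(tested, adj):
        r.p_adj_by = float(a)
    results = tested if include_non_deficit else \
        [r for r in tested if r.observed_hom < r.expected_hom]
    results.sort(key=lambda r: (r.p_adj_by, r.p_raw,
                                -r.expected_hom, r.allele.window.bp_start))
    return results


def merge_regions(results: list[DeficitResult], alpha: float = 0.05,
                  name_prefix: str = "HH-like") -> list[HaplotypeRegion]:
    """Merge significant windows (adjusted p < alpha) that share >=1 SNP and
    whose allele strings agree on the shared SNPs into named regions.

    The best window of a region is the lowest raw p, ties broken by larger
    expected count, then by leftmost bp_start.
    """
    sig = [r for r in results if r.p_adj_by < alpha]
    sig.sort(key=lambda r: (r.allele.window.chrom, r.allele.window.snp_start_index))
    regions: list[list[DeficitResult]] = []
    for r in sig:
        placed = False
        if regions:
            last = regions[-1]
            prev = last[-1]
            if _same_lineage(prev, r):
                last.append(r)
                placed = True
        if not placed:
            regions.append([r])
    out = []
    for i, members in enumerate(regions, start=1):
        best = min(members, key=lambda r: (
            r.p_raw, -r.expected_hom, r.allele.window.bp_start))
        out.append(HaplotypeRegion(
            name=f"{name_prefix}-{i:02d}",
            chrom=members[0].allele.window.chrom,
            bp_start=min(m.allele.window.bp_start for m in members),
            bp_end=max(m.allele.window.bp_end for m in members),
            best_window=best,
            supporting_windows=len(members),
            designs_detected=frozenset(m.design for m in members)))
    return out


def _same_lineage(a: DeficitResult, b: DeficitResult) -> bool:
    wa, wb = a.allele.window, b.allele.window
    if wa.chrom != wb.chrom:
        return False
    lo = max(wa.snp_start_index, wb.snp_start_index)
    hi = min(wa.snp_end_index, wb.snp_end_index)
    if hi - lo < 1:
        return False
    sa = a.allele.allele_string[lo - wa.snp_start_index:hi - wa.snp_start_index]
    sb = b.allele.allele_string[lo - wb.snp_start_index:hi - wb.snp_start_index]
    return sa == sb


def results_table(results: list[DeficitResult]) -> pd.DataFrame:
    """Tabular (Table-3-like) view of scan results."""
    return pd.DataFrame([{
        "chrom": r.allele.window.chrom,
        "bp_start": r.allele.window.bp_start,
        "bp_end": r.allele.window.bp_end,
        "design": r.design,
        "n_offspring": r.n_offspring_considered,
        "observed": r.observed_hom,
        "expected": round(r.expected_hom, 2),
        "deficient_pct": r.deficiency_pct,
        "allele_freq_pct": round(r.allele_freq_pct, 2),
        "p_raw": r.p_raw,
        "p_adj_by": r.p_adj_by,
        "allele": r.allele.allele_string,
    } for r in results])
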