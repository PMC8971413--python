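"""Candidate-variant filtering, LD to the haplotype, HWE test and ranking.

Implements the custom-array design rules used to shortlist candidate
causal variants inside an expanded haplotype region: hard-filter pass,
at most one homozygous-alt animal, at least one carrier of the target
breed, and no more than 75% of animals carrying the variant. Missing
genotypes are excluded pairwise from all denominators. Surviving
candidates are ranked by squared correlation (r^2) between their allele
dosage and the haplotype diplotype dosage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .deficit import HaplotypeRegion

logger = logging.getLogger(__name__)

#: Protein-changing consequence classes used as the default restriction.
PROTEIN_CHANGING = frozenset({
    "missense", "nonsense", "frameshift", "inframe_deletion",
    "inframe_insertion", "splice", "start_lost",
})

CONSEQUENCE_CLASSES = PROTEIN_CHANGING | {"other"}


@dataclass
class CandidateVariant:
    """One biallelic SNV/short indel with per-animal alt dosages
    (0/1/2, np.nan = missing) and breed labels."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    hard_filter_pass: bool
    dosages: np.ndarray
    breeds: np.ndarray
    gene: str = "."
    description: str = "."
    coding_change: str = "."

    @property
    def n_non_missing(self) -> int:
        return int(np.isfinite(self.dosages).sum())

    @property
    def n_carriers(self) -> int:
        return int(np.nansum(self.dosages >= 1))

    @property
    def n_hom_alt(self) -> int:
        return int(np.nansum(self.dosages == 2))

    @property
    def carrier_fraction(self) -> float:
        n = self.n_non_missing
        return self.n_carriers / n if n else np.nan


@dataclass
class RankedCandidate:
    variant: CandidateVariant
    r2_to_haplotype: float
    hwe_chi2_p: float
    rank: int = 0


def expand_region(region, flank_bp: int = 2_000_000,
                  chrom_length: int | None = None) -> tuple[str, int, int]:
    """Region span plus/minus ``flank_bp``, clipped to [1, chrom_length]."""
    if isinstance(region, HaplotypeRegion):
        chrom, start, end = region.chrom, region.bp_start, region.bp_end
    else:
        chrom, start, end = region
    lo = max(1, start - flank_bp)
    hi = end + flank_bp
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return chrom, lo, hi


def candidate_filter(variants: list[CandidateVariant], region,
                     breed_label: str = "Holstein",
                     max_carrier_fraction: float = 0.75, max_hom: int = 1,
                     require_consequence: frozenset | set | None = None,
                     flank_bp: int = 0) -> list[CandidateVariant]:
    """Apply the array-design selection rules inside a region.

    A variant is kept iff it passes hard filters, lies in the (optionally
    flank-expanded) region, has at least one carrier of ``breed_label``,
    carrier fraction <= ``max_carrier_fraction`` (inclusive), at most
    ``max_hom`` homozygous-alt animals, and — when ``require_consequence``
    is non-empty — a consequence in that set.
    """
    chrom, lo, hi = expand_region(region, flank_bp=flank_bp)
    labels_seen = set()
    for v in variants:
        labels_seen.update(v.breeds.tolist())
    if variants and breed_label not in labels_seen:
        raise ValueError(
            f"unknown breed label {breed_label!r}; labels seen: "
            f"{sorted(labels_seen)}")
    kept = []
    for v in variants:
        if not v.hard_filter_pass:
            continue
        if v.chrom != chrom or not (lo <= v.pos <= hi):
            continue
        breed_carrier = np.nansum(
            (v.dosages >= 1) & (v.breeds == breed_label)) >= 1
        if not breed_carrier:
            continue
        if not (v.carrier_fraction <= max_carrier_fraction):
            continue
        if v.n_hom_alt > max_hom:
            continue
        if require_consequence and v.consequence not in require_consequence:
            continue
        kept.append(v)
    return kept


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation between two dosage vectors over
    pairwise-complete animals; nan (with a warning) when undefined."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        warnings.warn("fewer than 2 pairwise-complete animals; r2 undefined")
        return float("nan")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant dosage vector; r2 undefined")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions from genotype
    counts, with expectations from the sample allele frequency."""
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be >= 0")
    n = counts.sum()
    if n == 0:
        raise ValueError("total genotype count is zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    nz = expected > 0
    chi2 = float(np.sum((counts[nz] - expected[nz]) ** 2 / expected[nz]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_p_from_dosage(dos: np.ndarray) -> float:
    d = dos[np.isfinite(dos)]
    if d.size == 0:
        return float("nan")
    return hwe_chisq(int((d == 0).sum()), int((d == 1).sum()),
                     int((d == 2).sum()))[1]


def rank_candidates(filtered: list[CandidateVariant],
                    haplotype_dosage) -> list[RankedCandidate]:
    """Rank filtered variants by r^2 to the haplotype diplotype (descending),
    ties by smaller carrier fraction, then by position."""
    if not filtered:
        raise ValueError("no filtered variants to rank")
    hd = np.asarray(haplotype_dosage, dtype=float)
    ranked = []
    for v in filtered:
        r2 = ld_r2(v.dosages, hd)
        if np.isnan(r2):
            continue
        ranked.append(RankedCandidate(
            variant=v, r2_to_haplotype=r2,
            hwe_chi2_p=_hwe_p_from_dosage(v.dosages)))
    if not ranked:
        logger.warning("no candidate with a defined r2; returning empty list")
        return []
    ranked.sort(key=lambda c: (-c.r2_to_haplotype,
                               c.variant.carrier_fraction, c.variant.pos))
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def design_rate(n_designed: int, n_selected: int) -> int:
    """Percent of initially selected variants that made it onto the array,
    rounded half-up to an integer percent."""
    if n_selected <= 0:
        raise ValueError("n_selected must be > 0")
    import math
    return int(math.floor(100.0 * n_designed / n_selected + 0.5))
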