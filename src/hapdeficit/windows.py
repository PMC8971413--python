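"""Sliding SNP-haplotype windows, window alleles and diplotype assignment.

A window haplotype is treated as an allele: the exact 0/1 string over the
window's SNPs on one chromosome copy. An animal's diplotype for a target
allele is the number of its two phased window haplotypes that match the
allele string exactly (0, 1 or 2 copies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import PhasedGenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 50

STATUS_LABELS = {0: "non-carrier", 1: "carrier", 2: "homozygous"}


@dataclass(frozen=True)
class WindowSpec:
    """One sliding window. SNP indices are global 0-based half-open indices
    into the genotype matrix's SNP table; bp coordinates are 1-based
    inclusive, taken from the first and last SNP of the window."""

    chrom: str
    snp_start_index: int
    snp_end_index: int
    window_size: int
    bp_start: int
    bp_end: int

    def __post_init__(self) -> None:
        if self.snp_end_index - self.snp_start_index != self.window_size:
            raise ValueError("window indices inconsistent with window_size")


@dataclass(frozen=True)
class HaplotypeAllele:
    """One observed allele (haplotype string) of a window."""

    window: WindowSpec
    allele_string: str  # '0'/'1' characters, length == window_size
    frequency: float
    count: int

    def as_array(self) -> np.ndarray:
        return np.frombuffer(self.allele_string.encode(), dtype=np.uint8) - ord("0")


@dataclass
class DiplotypeVector:
    """Per-animal copies of a target window allele, with carrier labels."""

    allele: HaplotypeAllele
    animal_ids: list[str]
    copies: np.ndarray  # int, values in {0, 1, 2}

    @property
    def status(self) -> list[str]:
        return [STATUS_LABELS[int(c)] for c in self.copies]


def enumerate_windows(genotypes: PhasedGenotypeMatrix,
                      window_size: int = DEFAULT_WINDOW_SIZE,
                      step: int = 1) -> list[WindowSpec]:
    """All sliding windows, per chromosome; chromosomes shorter than the
    window are skipped with a warning."""
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    snps = genotypes.snps
    out: list[WindowSpec] = []
    for chrom, grp in snps.groupby("chrom", sort=False):
        n = len(grp)
        if n < window_size:
            logger.warning("chromosome %s has %d SNPs (< window %d); skipped",
                           chrom, n, window_size)
            continue
        base = int(grp.index[0])
        pos = grp["pos"].to_numpy()
        for s in range(0, n - window_size + 1, step):
            out.append(WindowSpec(
                chrom=str(chrom),
                snp_start_index=base + s,
                snp_end_index=base + s + window_size,
                window_size=window_size,
                bp_start=int(pos[s]), bp_end=int(pos[s + window_size - 1])))
    return out


def _window_matrix(genotypes: PhasedGenotypeMatrix, window: WindowSpec) -> np.ndarray:
    if window.snp_start_index < 0 or window.snp_end_index > genotypes.n_snps:
        raise ValueError("window out of bounds")
    h = genotypes.haplotypes[:, :, window.snp_start_index:window.snp_end_index]
    return h.reshape(-1, window.window_size)  # (2*n_animals, w), interleaved


def window_allele_codes(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group identical haplotype rows of a window matrix.

    Returns ``(first_row, inverse, counts)``: for each distinct allele the
    index of one representative row, the allele index of every row, and
    the allele counts. Windows up to 64 SNPs are hashed exactly into a
    uint64 code (one bit per biallelic site); wider windows fall back to
    row-wise grouping.
    """
    n, w = mat.shape
    if w <= 64:
        codes = (mat.astype(np.uint64)
                 << np.arange(w, dtype=np.uint64)).sum(axis=1, dtype=np.uint64)
        _, first, inverse, counts = np.unique(
            codes, return_index=True, return_inverse=True, return_counts=True)
    else:
        _, first, inverse, counts = np.unique(
            mat, axis=0, return_index=True, return_inverse=True,
            return_counts=True)
    return first, inverse.ravel(), counts


def window_alleles(genotypes: PhasedGenotypeMatrix,
                   window: WindowSpec) -> list[HaplotypeAllele]:
    """Distinct haplotype strings in a window with their frequencies
    (count / 2*n_genotyped), sorted by descending frequency."""
    mat = _window_matrix(genotypes, window)
    first, _, counts = window_allele_codes(mat)
    total = mat.shape[0]
    order = np.argsort(-counts, kind="stable")
    return [HaplotypeAllele(
        window=window,
        allele_string="".join(map(str, mat[first[i]])),
        frequency=counts[i] / total,
        count=int(counts[i])) for i in order]


def assign_diplotypes(genotypes: PhasedGenotypeMatrix,
                      allele: HaplotypeAllele) -> DiplotypeVector:
    """Copies of the target allele per animal by exact string match against
    each of the animal's two phased window haplotypes."""
    if not genotypes.phase_known:
        raise ValueError("diplotype assignment requires phased genotypes")
    mat = _window_matrix(genotypes, allele.window)
    target = allele.as_array()
    match = (mat == target).all(axis=1).reshape(-1, 2)
    return DiplotypeVector(
        allele=allele,
        animal_ids=list(genotypes.animal_ids),
        copies=match.sum(axis=1).astype(int))
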