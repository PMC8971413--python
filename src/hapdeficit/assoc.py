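"""Haplotype- and SNP-trait association with a genomic relationship matrix.

Deregressed EBVs serve as pseudo-phenotypes in the single-random-effect
linear mixed model ``y = mu + beta*x + g + e`` with ``g ~ N(0, G sg2)``
and ``e ~ N(0, I se2)``, where G is the VanRaden genomic relationship
matrix. REML is exact and spectral: one eigendecomposition of G, then a
1-D optimization of the variance ratio delta = se2/sg2 (EMMA-style), so
fits are deterministic and cheap to repeat per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import PhasedGenotypeMatrix

logger = logging.getLogger(__name__)

_RIDGE = 1e-6


@dataclass
class GRMMatrix:
    animal_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.animal_ids),) * 2:
            raise ValueError("GRM shape inconsistent with animal ids")

    def subset(self, ids: list[str]) -> "GRMMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[a] for a in ids])
        return GRMMatrix(list(ids), self.matrix[np.ix_(idx, idx)])


@dataclass
class AssocResult:
    target: str
    trait_code: str
    n: int
    beta: float
    se: float
    p_value: float
    sigma2_g: float
    sigma2_e: float
    model: str  # 'LMM' or 'single-SNP-regression'

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def deregress(ebv, reliability, parent_average=None, weight_cap: float = 20.0):
    """Reliability-scaled deregression of EBVs into pseudo-phenotypes.

    Default: ``pseudo = ebv / r``, ``weight = r / (1 - r)`` capped at
    ``weight_cap``. When ``parent_average`` is given, the parent-average
    contribution is removed before scaling (Garrick-style):
    ``pseudo = pa + (ebv - pa) / r``.
    """
    ebv = np.asarray(ebv, dtype=float)
    r = np.asarray(reliability, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("reliability must lie in (0, 1]")
    if parent_average is None:
        pseudo = ebv / r
    else:
        pa = np.asarray(parent_average, dtype=float)
        pseudo = pa + (ebv - pa) / r
    with np.errstate(divide="ignore"):
        weight = np.where(r < 1, r / (1.0 - r), np.inf)
    weight = np.minimum(weight, weight_cap)
    if pseudo.ndim == 0:
        return float(pseudo), float(weight)
    return pseudo, weight


def compute_grm(genotypes) -> GRMMatrix:
    """VanRaden method-1 genomic relationship matrix.

    ``G = Z Z' / (2 sum p_j (1 - p_j))`` with ``Z = dosage - 2p`` and
    allele frequencies ``p`` estimated from the sample; monomorphic SNPs
    drop out of both Z and the denominator.
    """
    if isinstance(genotypes, PhasedGenotypeMatrix):
        dos = genotypes.dosage().astype(float)
        ids = list(genotypes.animal_ids)
    else:
        dos = np.asarray(genotypes, dtype=float)
        ids = [f"row{i}" for i in range(dos.shape[0])]
    if dos.shape[0] < 2:
        raise ValueError("GRM needs at least two animals")
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    Z = dos[:, poly] - 2 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    return GRMMatrix(ids, (Z @ Z.T) / denom)


class _EigenGRM:
    """Cached eigendecomposition of a GRM for repeated REML fits."""

    def __init__(self, grm: GRMMatrix):
        w, U = np.linalg.eigh(grm.matrix)
        if w.min() < -1e-8:
            logger.info("GRM not PSD (min eigenvalue %.3g); ridge %g applied",
                        w.min(), _RIDGE)
            w = w - w.min() + _RIDGE
        self.w = np.maximum(w, 0.0)
        self.U = U
        self.ids = grm.animal_ids


def _reml_neg_loglik(log_delta: float, ys: np.ndarray, Xs: np.ndarray,
                     w: np.ndarray) -> float:
    delta = np.exp(log_delta)
    d = w + delta
    Xw = Xs / d[:, None]
    XtX = Xs.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ ys)
    resid = ys - Xs @ beta
    n, p = Xs.shape
    rss = float(resid @ (resid / d))
    sign, logdet_xx = np.linalg.slogdet(XtX)
    return 0.5 * ((n - p) * np.log(rss) + np.log(d).sum() + logdet_xx)


def lmm_fit(y, x, grm, trait_code: str = "", target: str = "",
            model: str = "LMM", _eig: _EigenGRM | None = None) -> AssocResult:
    """Exact single-component REML fit of ``y = mu + beta*x + g + e``.

    Returns the Wald test for beta (per copy of the coded allele) together
    with the REML variance components.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(x)):
        raise ValueError("phenotypes and covariates must be finite")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; design is singular")
    eig = _eig if _eig is not None else _EigenGRM(grm)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    ys = eig.U.T @ y
    Xs = eig.U.T @ X

    grid = np.linspace(np.log(1e-5), np.log(1e5), 40)
    vals = [_reml_neg_loglik(g, ys, Xs, eig.w) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(_reml_neg_loglik, bounds=(lo, hi),
                                   args=(ys, Xs, eig.w), method="bounded")
    delta = float(np.exp(res.x))

    d = eig.w + delta
    Xw = Xs / d[:, None]
    XtX = Xs.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ ys)
    resid = ys - Xs @ beta
    p = X.shape[1]
    sigma2_g = float(resid @ (resid / d)) / (n - p)
    sigma2_e = sigma2_g * delta
    cov = sigma2_g * np.linalg.inv(XtX)
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se
    return AssocResult(
        target=target, trait_code=trait_code, n=n,
        beta=float(beta[1]), se=se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        sigma2_g=sigma2_g, sigma2_e=sigma2_e, model=model)


def _aligned(traits: pd.DataFrame, trait_code: str, grm: GRMMatrix,
             animal_ids: list[str]):
    tt = traits[traits["trait"] == trait_code]
    if tt.empty:
        raise ValueError(f"trait {trait_code!r} not present in trait table")
    tt = tt.set_index("animal_id")
    common = [a for a in animal_ids if a in tt.index and a in set(grm.animal_ids)]
    pseudo, _ = deregress(tt.loc[common, "ebv"].to_numpy(),
                          tt.loc[common, "reliability"].to_numpy())
    return common, pseudo


def haplotype_association(diplotypes, traits: pd.DataFrame, grm: GRMMatrix,
                          trait_code: str, min_informative: int = 30) -> AssocResult:
    """LMM association of risk-allele copies (additive 0/1/2 coding) with a
    deregressed-EBV pseudo-phenotype."""
    ids, pseudo = _aligned(traits, trait_code, grm, diplotypes.animal_ids)
    pos = {a: i for i, a in enumerate(diplotypes.animal_ids)}
    x = np.array([diplotypes.copies[pos[a]] for a in ids], dtype=float)
    n_informative = int((x > 0).sum())
    if np.ptp(x) == 0:
        raise ValueError("all animals carry 0 copies; covariate is constant")
    if n_informative < min_informative:
        raise ValueError(
            f"only {n_informative} carrier animals (< {min_informative}); "
            "association would be uninformative")
    sub = grm.subset(ids)
    return lmm_fit(pseudo, x, sub, trait_code=trait_code,
                   target=diplotypes.allele.allele_string, model="LMM")


@dataclass
class GwasScan:
    results: list[AssocResult]
    threshold: float
    trait_code: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "snp_id": r.target, "trait": r.trait_code, "n": r.n,
            "beta": r.beta, "se": r.se, "p_value": r.p_value,
        } for r in self.results])

    @property
    def hits(self) -> list[AssocResult]:
        return [r for r in self.results if r.p_value < self.threshold]


def gwas_scan(genotypes: PhasedGenotypeMatrix, traits: pd.DataFrame,
              grm: GRMMatrix, trait_code: str,
              alpha_bonferroni: float = 0.05, loco: bool = False) -> GwasScan:
    """Single-SNP LMM regressions with a Bonferroni genome-wide threshold
    alpha/m over the m polymorphic SNPs tested.

    By default every SNP is tested against the one supplied GRM. With
    ``loco=True`` each SNP is instead tested against a GRM built from the
    other chromosomes, so the polygenic random effect cannot absorb the
    tested SNP's own signal (proximal contamination). LOCO only pays off
    when each chromosome holds a small share of the genome; on few-
    chromosome genomes the excluded chromosome leaves enough unmodeled
    family covariance to inflate the null, so the single-GRM default is
    the calibrated choice there.
    """
    ids, pseudo = _aligned(traits, trait_code, grm, genotypes.animal_ids)
    rows = [genotypes.row(a) for a in ids]
    dos = genotypes.dosage().astype(float)[rows]
    chroms = genotypes.snps["chrom"].to_numpy()
    if loco and len(set(chroms)) < 2:
        logger.warning("single chromosome: LOCO GRM unavailable, "
                       "falling back to the full GRM")
        loco = False
    eigs: dict[str, _EigenGRM] = {}
    subs: dict[str, GRMMatrix] = {}
    if loco:
        for c in pd.unique(chroms):
            g = compute_grm(dos[:, chroms != c])
            g.animal_ids = list(ids)
            subs[c] = g
            eigs[c] = _EigenGRM(g)
    else:
        sub = grm.subset(ids)
        eig = _EigenGRM(sub)
    results = []
    for j in range(dos.shape[1]):
        x = dos[:, j]
        if np.ptp(x) == 0:
            continue
        if loco:
            sub, eig = subs[chroms[j]], eigs[chroms[j]]
        results.append(lmm_fit(pseudo, x, sub,
                               trait_code=trait_code,
                               target=str(genotypes.snps["snp_id"].iloc[j]),
                               model="single-SNP-regression", _eig=eig))
    m = len(results)
    threshold = alpha_bonferroni / m if m else np.nan
    return GwasScan(results=results, threshold=threshold, trait_code=trait_code)
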