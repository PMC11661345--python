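"""Gene-level association from variant summary statistics.

The SNP-wise mean model: a gene's statistic is the mean of squared
variant z-scores over the variants mapped to its body. Under the null,
z ~ N(0, R) with R the LD correlation matrix, so the statistic follows a
mixture of chi-squares (1/m) * sum_k lambda_k * chi2_1 with lambda_k the
eigenvalues of R. The upper-tail p-value is computed by Imhof's numeric
inversion of the characteristic function, switching to the Kuonen
saddlepoint approximation in the far tail, and mapped to a gene z-score
through the upper-tail probit.

Per-ancestry gene z-scores are meta-analyzed weighted by the square root
of the effective sample size.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .ld import LDPanel

logger = logging.getLogger(__name__)

EIGENVALUE_FLOOR = 1e-8
P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# quadratic-form tail probability


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    """P(sum lam_k chi2_1 >= q) by Imhof (1961) numerical integration."""

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return np.sin(theta) / (u * np.exp(log_rho))

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, limit=400, epsabs=1e-14, epsrel=1e-12
    )
    return 0.5 + val / np.pi


def _saddlepoint_logsf(q: float, lam: np.ndarray) -> float:
    """log P(sum lam_k chi2_1 >= q) via the Kuonen (1999) saddlepoint.

    Valid for q above the mean sum(lam); accurate deep into the tail where
    numeric integration loses all precision.
    """
    lam_max = lam.max()
    t_hi = 1.0 / (2.0 * lam_max) - 1e-12

    def kprime(t):
        return np.sum(lam / (1.0 - 2.0 * t * lam))

    t_lo = -1e2 / max(q, 1.0)
    while kprime(t_lo) > q:
        t_lo *= 2.0
        if t_lo < -1e12:
            return 0.0
    t = optimize.brentq(lambda s: kprime(s) - q, t_lo, t_hi, xtol=1e-14)
    k = -0.5 * np.sum(np.log1p(-2.0 * t * lam))
    kpp = np.sum(2.0 * lam ** 2 / (1.0 - 2.0 * t * lam) ** 2)
    if abs(t) < 1e-10:  # q at the mean; saddlepoint degenerates
        return np.log(0.5)
    w = np.sign(t) * np.sqrt(max(2.0 * (t * q - k), 0.0))
    v = t * np.sqrt(kpp)
    return float(stats.norm.logsf(w + np.log(v / w) / w))


def quadform_sf(q: float, lam) -> float:
    """Upper-tail probability of a positive-weighted chi-square mixture.

    Imhof integration carries absolute error of order 1e-5 from the
    oscillatory infinite integral, so it is trusted only for p >= 0.01;
    smaller tails use the saddlepoint approximation, whose relative error
    stays within a few percent arbitrarily deep. Results are clipped to
    [1e-300, 1].
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("need at least one positive eigenvalue")
    # negligible components slow the oscillatory integral's decay without
    # affecting the distribution at any relevant precision
    lam = lam[lam > 1e-7 * lam.sum()]
    if q <= 0:
        return 1.0
    if np.allclose(lam, lam[0]):
        return float(np.clip(stats.chi2.sf(q / lam[0], df=lam.size), P_FLOOR, 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        p = _imhof_sf(q, lam)
    if (not np.isfinite(p) or p < 1e-2) and q > lam.sum():
        p = np.exp(_saddlepoint_logsf(q, lam))
    return float(np.clip(p, P_FLOOR, 1.0))


# ---------------------------------------------------------------------------
# gene tests


def snpwise_mean_test(z, ld) -> tuple[float, float, float]:
    """SNP-wise mean gene test: mean squared z against its LD-mixture null.

    Returns ``(statistic, p, gene_z)`` with ``gene_z`` the upper-tail
    probit of p. Requires at least 3 variants; eigenvalues of the LD
    matrix are floored at 1e-8 before forming the null mixture.
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    if m < 3:
        raise ValueError("gene test requires at least 3 mapped variants")
    ld = np.asarray(ld, dtype=float)
    eig = np.linalg.eigvalsh(ld)
    if eig.min() < -1e-6:
        raise ValueError("LD matrix is not positive semi-definite")
    lam = np.maximum(eig, EIGENVALUE_FLOOR) / m
    stat = float(np.mean(z ** 2))
    p = quadform_sf(stat, lam)
    if p <= P_FLOOR:
        warnings.warn("gene p-value underflow; floored at 1e-300", RuntimeWarning)
    return stat, p, float(stats.norm.isf(p))


def map_variants_to_genes(
    stats_df: pd.DataFrame,
    genes: pd.DataFrame,
    maf_min: float = 0.01,
) -> dict[str, np.ndarray]:
    """Map common variants to every gene whose body contains them.

    Variants with minor-allele frequency <= ``maf_min`` are excluded
    first; interval containment is inclusive at both ends; overlapping
    genes each receive the variant. Returns row positions into
    ``stats_df`` per gene id.
    """
    maf = np.minimum(stats_df["FREQ"], 1.0 - stats_df["FREQ"])
    common = stats_df[maf > maf_min]
    out: dict[str, np.ndarray] = {}
    for chrom, grp in common.groupby("CHR"):
        grp = grp.sort_values("POS", kind="mergesort")
        pos = grp["POS"].to_numpy()
        rows = grp.index.to_numpy()
        for _, g in genes[genes["CHR"] == chrom].iterrows():
            lo = np.searchsorted(pos, g["START"], side="left")
            hi = np.searchsorted(pos, g["END"], side="right")
            out[g["GENE"]] = rows[lo:hi]
    for g in genes["GENE"]:
        out.setdefault(g, np.array([], dtype=int))
    return out


def score_genes(
    stats_df: pd.DataFrame,
    panel: LDPanel,
    genes: pd.DataFrame,
    maf_min: float = 0.01,
    min_variants: int = 3,
) -> pd.DataFrame:
    """SNP-wise mean gene scores for one ancestry.

    Genes with fewer than ``min_variants`` mapped common variants are not
    scored (NaN statistics, N_VARIANTS retained). Returns a frame indexed
    by gene with N_VARIANTS, STAT, P, Z columns.
    """
    mapping = map_variants_to_genes(stats_df, genes, maf_min)
    records = []
    for gene in genes["GENE"]:
        rows = mapping[gene]
        if len(rows) < min_variants:
            records.append((gene, len(rows), np.nan, np.nan, np.nan))
            continue
        sub = stats_df.loc[rows]
        z = (sub["BETA"] / sub["SE"]).to_numpy()
        ld = panel.corr(panel.index_of(sub["SNP"]))
        stat, p, gz = snpwise_mean_test(z, ld)
        records.append((gene, len(rows), stat, p, gz))
    return pd.DataFrame(
        records, columns=["GENE", "N_VARIANTS", "STAT", "P", "Z"]
    ).set_index("GENE")


def meta_gene_z(z_by_ancestry: list[tuple[pd.Series, float]]) -> pd.Series:
    """sqrt(N)-weighted meta-analysis of per-ancestry gene z-scores.

    z_meta = sum(w_i z_i) / sqrt(sum w_i^2) with w_i = sqrt(n_eff_i),
    summing over the ancestries in which a gene was scored; genes scored
    in a single ancestry carry that z through unchanged.
    """
    if not z_by_ancestry:
        raise ValueError("need at least one ancestry")
    frames = []
    for i, (z, n_eff) in enumerate(z_by_ancestry):
        w = np.sqrt(float(n_eff))
        frames.append(pd.DataFrame({f"wz{i}": w * z, f"w2_{i}": z.notna() * w ** 2}))
    df = pd.concat(frames, axis=1)
    wz = df[[c for c in df.columns if c.startswith("wz")]].sum(axis=1, min_count=1)
    w2 = df[[c for c in df.columns if c.startswith("w2_")]].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = wz / np.sqrt(w2.where(w2 > 0))
    out.name = "META_Z"
    return out
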