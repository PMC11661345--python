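"""Isolating statistically independent association signals.

Three stages, all operating on meta-analyzed summary statistics plus an
LD reference panel:

1. :func:`clump` — greedy PLINK-style clumping of genome-wide-significant
   variants (index = most significant unassigned variant; members share
   r² ≥ threshold within a physical window), clump spans padded and
   overlapping spans merged into regions.
2. :func:`cojo_select` — stepwise forward conditional/joint selection of
   independent hits within a region, in z-score space: conditional z for a
   candidate v given selected set S is the normalized multivariate-normal
   conditional ``(z_v - r_vS R_S^{-1} z_S) / sqrt(1 - r_vS R_S^{-1} r_Sv)``;
   joint effects for the final set are ``R_S^{-1}`` applied to the
   standardized marginal effects with per-variant effective sample sizes.
3. :func:`leave_one_out_condition` — for each selected hit, a regional
   summary-statistics table conditioned on all *other* hits, isolating
   that hit's signal for fine-mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


@dataclass
class Region:
    """A merged clump span (1-based inclusive bounds)."""

    chrom: int
    start: int
    end: int
    index_variants: list[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")


@dataclass
class CojoHit:
    """One independent hit with marginal and joint statistics."""

    snp: str
    chrom: int
    pos: int
    beta_marginal: float
    se_marginal: float
    p_marginal: float
    joint_beta: float
    joint_se: float
    joint_p: float
    order: int  # step at which the hit entered the model


@dataclass
class IndependentSignal:
    """One isolated signal: a lead hit plus regional conditional statistics.

    ``conditional_stats`` uses the standard summary-statistics dialect with
    BETA/SE/P replaced by their leave-one-hit-out conditional counterparts
    (for a single-hit region they equal the marginal statistics).
    """

    region: Region
    lead: str
    hits: list[CojoHit]
    conditional_stats: pd.DataFrame

    @property
    def signal_id(self) -> str:
        return self.lead


# ---------------------------------------------------------------------------
# clumping


def clump(
    meta_stats: pd.DataFrame,
    panel: LDPanel,
    p_thresh: float = GENOME_WIDE_P,
    r2_thresh: float = 0.1,
    window_bp: int = 3_000_000,
    pad_bp: int = 500_000,
) -> list[Region]:
    """Greedy LD clumping of significant variants into padded, merged regions.

    Repeatedly takes the most significant unassigned variant with
    p < ``p_thresh`` as an index and assigns to its clump every unassigned
    significant variant within ``window_bp`` of it with r² ≥ ``r2_thresh``.
    Each clump's span is expanded by ``pad_bp`` on both sides (floored at 1)
    and overlapping spans on a chromosome are merged, pooling their index
    variants (kept in significance order).
    """
    sig = meta_stats[meta_stats["P"] < p_thresh]
    if sig.empty:
        return []
    sig = sig.sort_values(["P", "CHR", "POS"], kind="mergesort").reset_index(drop=True)
    cols = panel.index_of(sig["SNP"])
    pos = sig["POS"].to_numpy()
    chrom = sig["CHR"].to_numpy()

    assigned = np.zeros(len(sig), dtype=bool)
    clumps: list[tuple[str, int, int, int]] = []  # (index snp, chrom, span lo, span hi)
    for i in range(len(sig)):
        if assigned[i]:
            continue
        cand = np.flatnonzero(
            ~assigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        )
        r = panel.r_with(cols[i], cols[cand])
        members = cand[r ** 2 >= r2_thresh]  # always includes i itself (r=1)
        assigned[members] = True
        span = pos[members]
        clumps.append((sig["SNP"][i], int(chrom[i]), int(span.min()), int(span.max())))

    # pad and merge per chromosome
    padded = [
        (c, max(1, lo - pad_bp), hi + pad_bp, snp) for snp, c, lo, hi in clumps
    ]
    padded.sort(key=lambda t: (t[0], t[1]))
    regions: list[Region] = []
    for c, lo, hi, snp in padded:
        if regions and regions[-1].chrom == c and lo <= regions[-1].end:
            regions[-1].end = max(regions[-1].end, hi)
            regions[-1].index_variants.append(snp)
        else:
            regions.append(Region(c, lo, hi, [snp]))
    return regions


# ---------------------------------------------------------------------------
# COJO-style stepwise selection


def joint_estimates(
    z: np.ndarray,
    r_mat: np.ndarray,
    n_eff: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Joint standardized effects for a selected set from marginal z-scores.

    Returns ``(beta_std, se_std, z_joint, p_joint)`` where
    ``beta_std = R^{-1} (z / sqrt(n))`` and
    ``se_std_j = sqrt((R^{-1})_jj / n_j)``.

    Raises ``numpy.linalg.LinAlgError`` if the LD matrix is singular.
    """
    z = np.asarray(z, dtype=float)
    n_eff = np.asarray(n_eff, dtype=float)
    r_inv = np.linalg.inv(np.asarray(r_mat, dtype=float))
    b = r_inv @ (z / np.sqrt(n_eff))
    se = np.sqrt(np.diag(r_inv) / n_eff)
    zj = b / se
    pj = np.clip(2.0 * stats.norm.sf(np.abs(zj)), 1e-300, 1.0)
    return b, se, zj, pj


def _conditional_z(
    z_all: np.ndarray,
    r_vs: np.ndarray,
    r_ss: np.ndarray,
    z_s: np.ndarray,
) -> np.ndarray:
    """Normalized MVN conditional z of each variant given the selected set.

    ``r_vs`` has one row per variant (correlations with the selected set).
    Variance residuals are floored at 1e-12; callers must overwrite the
    entries of the selected variants themselves (0/0 there).
    """
    alpha = np.linalg.solve(r_ss, z_s)
    num = z_all - r_vs @ alpha
    resid = 1.0 - np.einsum("ij,ij->i", r_vs, np.linalg.solve(r_ss, r_vs.T).T)
    return num / np.sqrt(np.clip(resid, 1e-12, None))


def _region_arrays(region: Region, meta_stats: pd.DataFrame, panel: LDPanel):
    reg = meta_stats[
        (meta_stats["CHR"] == region.chrom)
        & (meta_stats["POS"] >= region.start)
        & (meta_stats["POS"] <= region.end)
    ].reset_index(drop=True)
    if reg.empty:
        raise ValueError("region contains no variants")
    cols = panel.index_of(reg["SNP"])
    x = panel.standardized(cols)  # (n_samples, m)
    return reg, x


def cojo_select(
    region: Region,
    meta_stats: pd.DataFrame,
    panel: LDPanel,
    p_thresh: float = GENOME_WIDE_P,
    collinearity_r2: float = 0.9,
    max_hits: int = 32,
) -> list[CojoHit]:
    """Stepwise forward selection of independent hits within a region.

    Starts from the region's most significant variant, then repeatedly adds
    the variant with the smallest conditional p-value provided it is below
    ``p_thresh`` and it is not collinear with the selected set — both its
    pairwise r² with every selected variant and its multiple-regression R²
    on the whole set must stay below ``collinearity_r2``. After selection,
    joint estimates are computed for the set and hits with joint p above
    ``p_thresh`` are dropped (worst first, with re-estimation). A singular
    selected-set LD matrix drops the latest-entering offender with a
    warning.
    """
    reg, x = _region_arrays(region, meta_stats, panel)
    n_samp = x.shape[0]
    z = (reg["BETA"] / reg["SE"]).to_numpy()
    p = reg["P"].to_numpy()
    n_eff = reg["N_EFF"].to_numpy(dtype=float)

    if p.min() >= p_thresh:
        return []
    selected = [int(np.argmin(p))]
    while len(selected) < max_hits:
        r_vs = x.T @ x[:, selected] / n_samp          # (m, k)
        r_ss = r_vs[selected, :]
        try:
            zc = _conditional_z(z, r_vs, r_ss, z[selected])
            multiple_r2 = np.einsum(
                "ij,ij->i", r_vs, np.linalg.solve(r_ss, r_vs.T).T
            )
        except np.linalg.LinAlgError:
            logger.warning("singular LD among selected hits; stopping selection")
            break
        pc = 2.0 * stats.norm.sf(np.abs(zc))
        pc[selected] = 1.0
        pc[(r_vs ** 2).max(axis=1) >= collinearity_r2] = 1.0
        pc[multiple_r2 >= collinearity_r2] = 1.0
        best = int(np.argmin(pc))
        if pc[best] >= p_thresh:
            break
        selected.append(best)

    # joint model; drop joint-insignificant hits, worst first
    order = {s: k for k, s in enumerate(selected)}
    while selected:
        r_ss = x[:, selected].T @ x[:, selected] / n_samp
        try:
            b_std, se_std, zj, pj = joint_estimates(z[selected], r_ss, n_eff[selected])
        except np.linalg.LinAlgError:
            drop = max(selected, key=lambda s: order[s])
            logger.warning("singular selected-set LD; dropping later hit %s",
                           reg["SNP"][drop])
            selected.remove(drop)
            continue
        if len(selected) > 1 and pj.max() > p_thresh:
            worst = selected[int(np.argmax(pj))]
            selected.remove(worst)
            continue
        if len(selected) == 1 and pj[0] > p_thresh:
            return []
        break
    if not selected:
        return []

    f = panel.freqs()[panel.index_of(reg["SNP"][selected])]
    w = np.sqrt(np.clip(2.0 * f * (1.0 - f), 1e-12, None))
    hits = [
        CojoHit(
            snp=reg["SNP"][s],
            chrom=int(reg["CHR"][s]),
            pos=int(reg["POS"][s]),
            beta_marginal=float(reg["BETA"][s]),
            se_marginal=float(reg["SE"][s]),
            p_marginal=float(reg["P"][s]),
            joint_beta=float(b_std[k] / w[k]),
            joint_se=float(se_std[k] / w[k]),
            joint_p=float(pj[k]),
            order=order[s],
        )
        for k, s in enumerate(selected)
    ]
    hits.sort(key=lambda h: h.order)
    return hits


def leave_one_out_condition(
    region: Region,
    hits: list[CojoHit],
    meta_stats: pd.DataFrame,
    panel: LDPanel,
) -> list[IndependentSignal]:
    """Isolate each hit by conditioning the region on all other hits.

    With a single hit the conditional table equals the marginal table.
    Conditioning variants themselves are set to z = 0, p = 1. The
    conditional beta is reported as ``z_cond * SE`` (allele scale, marginal
    SE retained).
    """
    if not hits:
        raise ValueError("need at least one selected hit")
    reg, x = _region_arrays(region, meta_stats, panel)
    n_samp = x.shape[0]
    z = (reg["BETA"] / reg["SE"]).to_numpy()
    snp_pos = {s: i for i, s in enumerate(reg["SNP"])}

    signals = []
    for h in hits:
        others = [snp_pos[o.snp] for o in hits if o.snp != h.snp]
        table = reg.copy()
        if others:
            r_vs = x.T @ x[:, others] / n_samp
            r_ss = r_vs[others, :]
            zc = _conditional_z(z, r_vs, r_ss, z[others])
            zc[others] = 0.0
            table["BETA"] = zc * table["SE"]
            table["P"] = np.clip(2.0 * stats.norm.sf(np.abs(zc)), 1e-300, 1.0)
        signals.append(IndependentSignal(region, h.snp, hits, table))
    return signals
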