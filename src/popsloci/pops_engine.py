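"""Polygenic priority scoring (PoPS-style).

Gene-level association z-scores are regressed on a large gene x feature
matrix: features passing a marginal-association screen are combined by
ridge regression fit with leave-one-chromosome-out (LOCO) folds, so a
gene's score is predicted by a model that never saw its chromosome's
association signal. Per-ancestry scores are meta-analyzed by a
sqrt(effective-N)-weighted mean and summarized as genome-wide
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import RidgeCV

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = np.logspace(-2, 6, 17)


def select_features(
    gene_z: pd.Series,
    features: pd.DataFrame,
    alpha: float = 0.05,
) -> np.ndarray:
    """Marginal feature screen against gene association z-scores.

    Each feature column is regressed (with intercept) on the gene z
    vector; column indices with marginal slope p < ``alpha`` are returned.
    Constant features are skipped with a warning.
    """
    z = gene_z.reindex(features.index)
    ok = z.notna().to_numpy()
    y = z.to_numpy(dtype=float)[ok]
    x = features.to_numpy(dtype=float)[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 scored genes for the feature screen")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    constant = sx == 0
    if constant.any():
        logger.warning("skipping %d constant feature(s)", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (n * np.where(constant, np.nan, sx) * sy)
    r2 = np.clip(r ** 2, 0.0, 1.0 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[constant] = 1.0
    return np.flatnonzero(p < alpha)


@dataclass
class PoPSFit:
    """LOCO ridge fit: per-chromosome models and out-of-chromosome scores."""

    selected: np.ndarray
    alphas: dict = field(default_factory=dict)       # chrom -> chosen penalty
    coefs: dict = field(default_factory=dict)        # chrom -> standardized coefs
    intercepts: dict = field(default_factory=dict)   # chrom -> intercept
    scores: pd.Series | None = None


def loco_ridge(
    gene_z: pd.Series,
    features: pd.DataFrame,
    selected: np.ndarray,
    gene_chrom: pd.Series,
    alpha_grid: np.ndarray | None = None,
) -> PoPSFit:
    """Leave-one-chromosome-out ridge prediction of gene z from features.

    For each chromosome c the model is fit on genes *not* on c (features
    standardized with training-fold statistics only; penalty chosen by
    efficient leave-one-out cross-validation on the training fold) and
    used to score every gene on c — so chromosome-c scores are a function
    of non-c gene z-scores only. With an empty feature set all scores on c
    equal the training-fold mean z.
    """
    alpha_grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    chroms = pd.unique(gene_chrom.reindex(features.index))
    if len(chroms) < 2:
        raise ValueError("leave-one-chromosome-out requires at least 2 chromosomes")
    z = gene_z.reindex(features.index)
    chrom = gene_chrom.reindex(features.index)
    x_all = features.to_numpy(dtype=float)[:, np.asarray(selected, dtype=int)]

    fit = PoPSFit(selected=np.asarray(selected, dtype=int))
    scores = pd.Series(np.nan, index=features.index, dtype=float, name="POPS")
    for c in chroms:
        test = (chrom == c).to_numpy()
        train = ~test & z.notna().to_numpy()
        if train.sum() == 0:
            raise ValueError(
                f"chromosome {c} holds every scored gene; LOCO fit impossible"
            )
        y_tr = z.to_numpy(dtype=float)[train]
        if x_all.shape[1] == 0:
            fit.alphas[c] = np.nan
            fit.coefs[c] = np.zeros(0)
            fit.intercepts[c] = float(y_tr.mean())
            scores.iloc[np.flatnonzero(test)] = y_tr.mean()
            continue
        x_tr = x_all[train]
        mu = x_tr.mean(axis=0)
        sd = x_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        model = RidgeCV(alphas=alpha_grid, fit_intercept=True)
        model.fit((x_tr - mu) / sd, y_tr)
        fit.alphas[c] = float(model.alpha_)
        fit.coefs[c] = model.coef_.copy()
        fit.intercepts[c] = float(model.intercept_)
        scores.iloc[np.flatnonzero(test)] = model.predict((x_all[test] - mu) / sd)
    fit.scores = scores
    return fit


def meta_pops(
    scores_by_ancestry: list[tuple[pd.Series, float]],
    scheme: str = "mean",
) -> pd.Series:
    """sqrt(N)-weighted combination of per-ancestry PoPS scores.

    Scores are predictions rather than test statistics, so the default is
    a convex weighted mean: sum(w_i s_i) / sum(w_i) over the ancestries
    scoring each gene, with w_i = sqrt(n_eff_i). ``scheme="z"`` applies
    the z-statistic combination sum(w_i s_i) / sqrt(sum w_i^2) instead.
    """
    if scheme not in ("mean", "z"):
        raise ValueError(f"unknown PoPS meta scheme {scheme!r}")
    if not scores_by_ancestry:
        raise ValueError("need at least one ancestry")
    num = None
    den = None
    for s, n_eff in scores_by_ancestry:
        w = np.sqrt(float(n_eff))
        ws = (w * s).fillna(0.0)
        wmask = s.notna() * (w if scheme == "mean" else w ** 2)
        num = ws if num is None else num.add(ws, fill_value=0.0)
        den = wmask if den is None else den.add(wmask, fill_value=0.0)
    if scheme == "z":
        den = np.sqrt(den)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den.where(den > 0)
    out.name = "POPS_META"
    return out


def pops_percentile(scores: pd.Series) -> pd.Series:
    """Genome-wide percentile of meta PoPS scores in [0, 1].

    Rank-based with average ranks for ties, scaled so the smallest score
    maps to 0 and the largest to 1; with all scores tied, every gene sits
    at 0.5.
    """
    vals = scores.dropna()
    if len(vals) < 2:
        raise ValueError("percentiles require at least 2 scored genes")
    ranks = stats.rankdata(vals.to_numpy(), method="average")
    pct = (ranks - 1.0) / (len(vals) - 1.0)
    out = pd.Series(np.nan, index=scores.index, dtype=float, name="POPS_PERCENTILE")
    out.loc[vals.index] = pct
    return out
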