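"""Wakefield approximate-Bayes-factor fine-mapping.

For one isolated signal under a single-causal-variant assumption:
log-ABF per variant, posterior inclusion probabilities (PIPs) by
log-space normalization, the minimal 95% credible set, its PIP-weighted
center, and the final locus window with overlapping genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .signal_isolation import IndependentSignal

DEFAULT_PRIOR_SD = 0.2  # effect-size prior SD on the log-odds scale
DEFAULT_COVERAGE = 0.95
DEFAULT_LOCUS_PAD = 300_000


def wakefield_labf(z, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Log approximate Bayes factor for association at a single variant.

    With V = se², W = prior_sd² and r = W / (W + V):
    lABF = 0.5 * (log(1 - r) + r * z²).
    """
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    r = prior_sd ** 2 / (prior_sd ** 2 + se ** 2)
    return 0.5 * (np.log1p(-r) + r * z ** 2)


def pips_from_labf(labf) -> np.ndarray:
    """Posterior inclusion probabilities: softmax of lABFs in log space."""
    labf = np.asarray(labf, dtype=float)
    return np.exp(labf - logsumexp(labf))


@dataclass
class CredibleSet:
    """95% credible set for one isolated signal.

    ``table`` holds one row per regional variant (SNP, POS, LABF, PIP,
    IN_CS); PIPs sum to 1 over the whole table. ``weighted_center`` is the
    PIP-weighted average position of the member variants (renormalized
    within the set).
    """

    signal_id: str
    chrom: int
    table: pd.DataFrame
    coverage: float
    weighted_center: float

    @property
    def members(self) -> pd.DataFrame:
        return self.table[self.table["IN_CS"]]


@dataclass
class Locus:
    """Gene search window around a credible set (1-based inclusive)."""

    locus_id: str
    signal_id: str
    chrom: int
    start: int
    end: int
    genes: list[str]


def abf_finemap(
    z: np.ndarray,
    se: np.ndarray,
    pos: np.ndarray,
    coverage: float = DEFAULT_COVERAGE,
    prior_sd: float = DEFAULT_PRIOR_SD,
    tie_tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Core single-causal fine-mapping on plain arrays.

    Returns ``(labf, pip, in_cs, achieved_coverage, weighted_center)``.
    The credible set is the minimal prefix of variants, sorted by PIP
    descending (position ascending within ties), whose cumulative PIP
    reaches ``coverage``; PIP ties straddling the boundary are all
    included.
    """
    if len(z) == 0:
        raise ValueError("signal contains no variants")
    labf = wakefield_labf(z, se, prior_sd)
    pip = pips_from_labf(labf)
    order = np.lexsort((pos, -pip))
    csum = np.cumsum(pip[order])
    k = int(np.searchsorted(csum, coverage - 1e-12)) + 1
    k = min(k, len(pip))
    while k < len(pip) and pip[order[k]] >= pip[order[k - 1]] - tie_tol:
        k += 1
    in_cs = np.zeros(len(pip), dtype=bool)
    in_cs[order[:k]] = True
    achieved = float(pip[in_cs].sum())
    center = float(np.sum(pip[in_cs] * pos[in_cs]) / pip[in_cs].sum())
    return labf, pip, in_cs, achieved, center


def credible_set(
    signal: IndependentSignal,
    coverage: float = DEFAULT_COVERAGE,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> CredibleSet:
    """Credible set for a signal's leave-one-out conditional statistics."""
    cond = signal.conditional_stats
    if cond.empty:
        raise ValueError("signal contains no variants")
    z = (cond["BETA"] / cond["SE"]).to_numpy()
    labf, pip, in_cs, achieved, center = abf_finemap(
        z, cond["SE"].to_numpy(), cond["POS"].to_numpy(), coverage, prior_sd
    )
    pip_cs = np.where(in_cs, pip / pip[in_cs].sum(), 0.0)
    table = pd.DataFrame(
        {
            "SNP": cond["SNP"],
            "POS": cond["POS"],
            "LABF": labf,
            "PIP": pip,
            "PIP_CS": pip_cs,
            "IN_CS": in_cs,
        }
    )
    return CredibleSet(
        signal_id=signal.signal_id,
        chrom=int(cond["CHR"].iloc[0]),
        table=table,
        coverage=achieved,
        weighted_center=center,
    )


def define_locus(
    cs: CredibleSet,
    genes: pd.DataFrame,
    pad: int = DEFAULT_LOCUS_PAD,
    locus_id: str | None = None,
) -> Locus:
    """Locus window = credible-set span ± ``pad``, with overlapping genes.

    Gene bodies overlap the window under closed-interval (inclusive)
    comparison in 1-based coordinates; the start is floored at 1. A locus
    may legitimately contain zero genes.
    """
    mpos = cs.members["POS"]
    start = max(1, int(mpos.min()) - pad)
    end = int(mpos.max()) + pad
    hit = genes[
        (genes["CHR"] == cs.chrom) & (genes["START"] <= end) & (genes["END"] >= start)
    ]
    return Locus(
        locus_id=locus_id or f"locus_{cs.signal_id}",
        signal_id=cs.signal_id,
        chrom=cs.chrom,
        start=start,
        end=end,
        genes=list(hit["GENE"]),
    )
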