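"""Variant-level summary statistics: harmonization, QC, meta-analysis.

Tables use the TSV dialect written by :mod:`popsloci.synthetic_data`
(columns CHR, POS, SNP, A1, A2, FREQ, BETA, SE, P, N_EFF; A1 is the
effect allele, positions are 1-based).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["CHR", "POS", "SNP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N_EFF"]

_PALINDROMES = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class QCReport:
    """Bookkeeping for variant filtering steps."""

    n_input: int = 0
    n_removed_absdiff: int = 0
    n_removed_foldchange: int = 0
    n_removed_unmatched: int = 0
    n_removed_ambiguous: int = 0
    n_remaining: int = 0

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_absdiff
            + self.n_removed_foldchange
            + self.n_removed_unmatched
            + self.n_removed_ambiguous
        )
        if self.n_input != self.n_remaining + removed:
            raise ValueError("QCReport counts do not add up")

    def to_dict(self) -> dict:
        return asdict(self)


def harmonize(stats_df: pd.DataFrame, panel: LDPanel) -> tuple[pd.DataFrame, QCReport]:
    """Match summary statistics to a reference panel and orient alleles.

    Variants are matched by chromosome + position + (unordered) allele
    pair. Where the study's effect allele is the panel's A2, the record is
    flipped (beta negated, frequency complemented) so every retained row
    reports effects on the panel's A1 allele, and the panel's SNP id is
    adopted. Strand-ambiguous (A/T, C/G) variants with effect-allele
    frequency in [0.4, 0.6] are dropped; unmatched variants are dropped
    and counted.
    """
    df = stats_df.copy()
    n_input = len(df)

    hi = np.maximum(df["A1"].to_numpy(), df["A2"].to_numpy())
    lo = np.minimum(df["A1"].to_numpy(), df["A2"].to_numpy())
    key = pd.DataFrame({"CHR": df["CHR"], "POS": df["POS"], "HI": hi, "LO": lo})
    dup = key.duplicated(keep=False)
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate variant record at {first['CHR']}:{first['POS']} "
            f"({first['A1']}/{first['A2']}), first id {first['SNP']!r}"
        )

    pal = np.array(
        [frozenset((a1, a2)) in _PALINDROMES for a1, a2 in zip(df["A1"], df["A2"])]
    )
    ambiguous = pal & df["FREQ"].between(0.4, 0.6).to_numpy()
    n_ambiguous = int(ambiguous.sum())
    df = df[~ambiguous]

    vm = panel.variants[["CHR", "POS", "SNP", "A1", "A2"]].rename(
        columns={"SNP": "SNP_PANEL", "A1": "A1_PANEL", "A2": "A2_PANEL"}
    )
    merged = df.merge(vm, on=["CHR", "POS"], how="left")
    direct = (merged["A1"] == merged["A1_PANEL"]) & (merged["A2"] == merged["A2_PANEL"])
    swapped = (merged["A1"] == merged["A2_PANEL"]) & (merged["A2"] == merged["A1_PANEL"])
    matched = (direct | swapped).fillna(False)
    n_unmatched = int((~matched).sum())

    out = merged[matched].copy()
    flip = swapped[matched].to_numpy()
    out.loc[flip, "BETA"] = -out.loc[flip, "BETA"]
    out.loc[flip, "FREQ"] = 1.0 - out.loc[flip, "FREQ"]
    out["A1"] = out["A1_PANEL"]
    out["A2"] = out["A2_PANEL"]
    out["SNP"] = out["SNP_PANEL"]
    out = (
        out[SUMSTATS_COLUMNS]
        .sort_values(["CHR", "POS"], kind="mergesort")
        .reset_index(drop=True)
    )
    report = QCReport(
        n_input=n_input,
        n_removed_unmatched=n_unmatched,
        n_removed_ambiguous=n_ambiguous,
        n_remaining=len(out),
    )
    return out, report


def af_qc(
    stats_df: pd.DataFrame,
    panel_freqs: pd.Series,
    abs_thresh: float = 0.1,
    fold_thresh: float = 12.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Allele-frequency QC against reference-panel frequencies.

    Applied sequentially: first remove variants whose effect-allele
    frequency differs from the reference frequency by more than
    ``abs_thresh``, then remove survivors whose frequency ratio (in either
    direction) exceeds ``fold_thresh``. Reference frequencies of exactly 0
    or 1 fail the fold rule.

    Parameters
    ----------
    panel_freqs:
        Effect-allele (A1) frequency in the reference panel, indexed by SNP.
    """
    df = stats_df.copy()
    n_input = len(df)
    ref = df["SNP"].map(panel_freqs)
    if ref.isna().any():
        missing = df.loc[ref.isna(), "SNP"].iloc[0]
        raise KeyError(f"no reference frequency for variant {missing!r}")
    ref = ref.to_numpy(dtype=float)
    eaf = df["FREQ"].to_numpy(dtype=float)

    abs_fail = np.abs(eaf - ref) > abs_thresh
    n_abs = int(abs_fail.sum())
    df, ref, eaf = df[~abs_fail], ref[~abs_fail], eaf[~abs_fail]

    degenerate = (ref <= 0.0) | (ref >= 1.0)
    if degenerate.any():
        logger.info("removing %d variants with degenerate reference frequency "
                    "under the fold rule", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.maximum(eaf / ref, ref / eaf)
    fold_fail = degenerate | (fold > fold_thresh)
    n_fold = int(fold_fail.sum())
    out = df[~fold_fail].reset_index(drop=True)

    report = QCReport(
        n_input=n_input,
        n_removed_absdiff=n_abs,
        n_removed_foldchange=n_fold,
        n_remaining=len(out),
    )
    return out, report


def meta_fixed_effects(
    stats_by_ancestry: list[pd.DataFrame],
    scheme: str = "stderr",
) -> pd.DataFrame:
    """Fixed-effects meta-analysis across ancestries.

    With the default effect-based scheme (``"stderr"``):
    beta_meta = sum(beta_i / se_i^2) / sum(1 / se_i^2), se_meta =
    sqrt(1 / sum(1 / se_i^2)), p from the two-sided normal tail of
    beta_meta / se_meta. The ``"samplesize"`` scheme instead combines
    z-scores weighted by sqrt(N_eff) (and back-computes beta/SE on the
    combined scale). Variants present in a single study carry that
    study's statistics; effective sample sizes are summed and frequencies
    averaged with N_eff weights. Inputs must already be harmonized to a
    common effect-allele orientation.
    """
    if scheme not in ("stderr", "samplesize"):
        raise ValueError(f"unknown meta-analysis scheme {scheme!r}")
    if not stats_by_ancestry:
        raise ValueError("need at least one summary-statistics table")
    if len(stats_by_ancestry) == 1:
        return stats_by_ancestry[0][SUMSTATS_COLUMNS].reset_index(drop=True).copy()

    cat = pd.concat(stats_by_ancestry, ignore_index=True)
    alleles = cat.groupby("SNP")[["CHR", "POS", "A1", "A2"]].nunique()
    conflict = (alleles > 1).any(axis=1)
    if conflict.any():
        raise ValueError(
            f"conflicting coordinates/alleles after harmonization for "
            f"variant {conflict.idxmax()!r}"
        )

    if scheme == "stderr":
        w = 1.0 / cat["SE"] ** 2
        wb = w * cat["BETA"]
    else:  # sample-size weighting on z-scores
        w = cat["N_EFF"].astype(float)
        wb = np.sqrt(w) * (cat["BETA"] / cat["SE"])
    cat = cat.assign(_W=w, _WB=wb, _NF=cat["N_EFF"] * cat["FREQ"])
    g = cat.groupby("SNP", sort=False)
    agg = g.agg(
        CHR=("CHR", "first"),
        POS=("POS", "first"),
        A1=("A1", "first"),
        A2=("A2", "first"),
        _W=("_W", "sum"),
        _WB=("_WB", "sum"),
        _NF=("_NF", "sum"),
        N_EFF=("N_EFF", "sum"),
    )
    if scheme == "stderr":
        beta = agg["_WB"] / agg["_W"]
        se = 1.0 / np.sqrt(agg["_W"])
        z = beta / se
    else:
        z = agg["_WB"] / np.sqrt(agg["_W"])
        f = agg["_NF"] / agg["N_EFF"]
        se = 1.0 / np.sqrt(agg["N_EFF"] * 2.0 * f * (1.0 - f))
        beta = z * se
    out = pd.DataFrame(
        {
            "CHR": agg["CHR"],
            "POS": agg["POS"],
            "SNP": agg.index,
            "A1": agg["A1"],
            "A2": agg["A2"],
            "FREQ": agg["_NF"] / agg["N_EFF"],
            "BETA": beta,
            "SE": se,
            "P": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
            "N_EFF": agg["N_EFF"],
        }
    )
    return (
        out.sort_values(["CHR", "POS"], kind="mergesort")
        .reset_index(drop=True)[SUMSTATS_COLUMNS]
    )
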