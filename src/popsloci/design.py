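"""Multi-ancestry study-design arithmetic.

Helpers for sizing a mixed-ancestry LD reference panel so its composition
matches the GWAS being analyzed: the share of each ancestry is its share
of the total effective sample size, and the panel counts are anchored on
the ancestry with the fewest available reference samples.
"""

from __future__ import annotations


def effective_sample_share(n_effs: dict[str, float]) -> dict[str, float]:
    """Share of the combined effective sample size per ancestry."""
    total = sum(n_effs.values())
    if total <= 0:
        raise ValueError("effective sample sizes must be positive")
    return {k: v / total for k, v in n_effs.items()}


def matched_panel_size(
    n_ref_anchor: int,
    n_eff_anchor: float,
    n_eff_target: float,
) -> int:
    """Reference-panel count for one ancestry matching GWAS proportions.

    Given that the anchor ancestry contributes ``n_ref_anchor`` panel
    members, the target ancestry should contribute
    ``n_ref_anchor * n_eff_target / n_eff_anchor`` members (rounded) for
    the panel mixture to mirror the effective-sample-size ratio.
    """
    if n_ref_anchor <= 0 or n_eff_anchor <= 0 or n_eff_target <= 0:
        raise ValueError("counts and effective sample sizes must be positive")
    return round(n_ref_anchor * n_eff_target / n_eff_anchor)
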