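"""Per-locus gene prioritization and comparison with external predictions.

Decision rule per locus:

* Criterion A ("pops_nearest"): one gene is both the nearest gene to the
  credible set's PIP-weighted center *and* carries the top meta PoPS score
  among the locus genes.
* Criterion B ("nonsynonymous"): a gene whose non-synonymous credible-set
  variants carry summed PIP above a threshold (default 0.5).

If both fire — for the same or different genes — the criterion-B gene is
the sole prioritized gene; if only A fires, its gene is prioritized; a
locus whose nearest gene and top-PoPS gene differ, with no qualifying
non-synonymous variant, yields no call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .finemapping import CredibleSet, Locus

BASIS_POPS_NEAREST = "pops_nearest"
BASIS_NONSYN = "nonsynonymous"


def gene_distance(gene, center: float) -> float:
    """Distance in bp from a position to a gene body (0 if inside).

    ``gene`` is any mapping with CHR, START, END; raises if the gene and
    the center's chromosome differ (pass ``center_chrom``-checked input).
    """
    start, end = float(gene["START"]), float(gene["END"])
    if start <= center <= end:
        return 0.0
    return float(min(abs(center - start), abs(center - end)))


@dataclass
class LocusCall:
    """Prioritization outcome for one locus."""

    locus_id: str
    signal_id: str
    candidates: pd.DataFrame  # GENE, DISTANCE, POPS, POPS_PERCENTILE, NEAREST, TOP_POPS, NONSYN_PIP
    prioritized_gene: str | None
    basis: str | None


def call_locus(
    locus: Locus,
    cs: CredibleSet,
    gene_table: pd.DataFrame,
    pops_meta: pd.Series,
    pops_pct: pd.Series,
    nonsyn_map: pd.DataFrame,
    nonsyn_pip_thresh: float = 0.5,
    nonsyn_rule: str = "sum",
) -> LocusCall:
    """Apply the prioritization rule to one locus.

    Ties: equidistant nearest genes break toward higher meta PoPS then
    lexicographic gene id; tied top PoPS breaks lexicographically. Genes
    without a PoPS score remain candidates but can never hold the
    top-PoPS flag. ``nonsyn_map`` has columns SNP, GENE.

    ``nonsyn_rule``: the non-synonymous PIP per gene is the ``"sum"``
    (default) or the ``"max"`` (single-variant reading) over that gene's
    non-synonymous credible-set variants.
    """
    if nonsyn_rule not in ("sum", "max"):
        raise ValueError(f"unknown nonsyn_rule {nonsyn_rule!r}")
    genes = gene_table[gene_table["GENE"].isin(locus.genes)].copy()
    if genes.empty:
        return LocusCall(locus.locus_id, locus.signal_id,
                         _empty_candidates(), None, None)
    if (genes["CHR"] != locus.chrom).any():
        raise ValueError("locus gene on a different chromosome than the signal")

    cand = pd.DataFrame({"GENE": genes["GENE"].to_numpy()})
    cand["DISTANCE"] = [
        gene_distance(g, cs.weighted_center) for _, g in genes.iterrows()
    ]
    cand["POPS"] = cand["GENE"].map(pops_meta)
    cand["POPS_PERCENTILE"] = cand["GENE"].map(pops_pct)

    # nearest flag (exactly one gene)
    order = cand.assign(_negpops=-cand["POPS"].fillna(-np.inf)).sort_values(
        ["DISTANCE", "_negpops", "GENE"], kind="mergesort"
    )
    nearest_gene = order["GENE"].iloc[0]
    cand["NEAREST"] = cand["GENE"] == nearest_gene

    scored = cand[cand["POPS"].notna()]
    if scored.empty:
        top_gene = None
    else:
        best = scored[scored["POPS"] == scored["POPS"].max()]
        top_gene = best["GENE"].min()
    cand["TOP_POPS"] = cand["GENE"] == top_gene

    members = cs.members[["SNP", "PIP"]]
    ns = members.merge(nonsyn_map, on="SNP")
    ns = ns[ns["GENE"].isin(cand["GENE"])]
    pip_by_gene = ns.groupby("GENE")["PIP"].agg(nonsyn_rule)
    cand["NONSYN_PIP"] = cand["GENE"].map(pip_by_gene).fillna(0.0)

    a_gene = nearest_gene if (top_gene is not None and top_gene == nearest_gene) else None
    b = cand[cand["NONSYN_PIP"] > nonsyn_pip_thresh]
    if not b.empty:
        b = b.sort_values(["NONSYN_PIP", "GENE"], ascending=[False, True],
                          kind="mergesort")
        prioritized, basis = b["GENE"].iloc[0], BASIS_NONSYN
    elif a_gene is not None:
        prioritized, basis = a_gene, BASIS_POPS_NEAREST
    else:
        prioritized, basis = None, None
    return LocusCall(locus.locus_id, locus.signal_id, cand, prioritized, basis)


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["GENE", "DISTANCE", "POPS", "POPS_PERCENTILE",
                 "NEAREST", "TOP_POPS", "NONSYN_PIP"]
    )


def rescale_external(preds: pd.DataFrame) -> pd.DataFrame:
    """Cap per-locus external causal probabilities at a total of 100%.

    ``preds`` has columns LOCUS, GENE, PROB. Loci whose probabilities sum
    above 1 are rescaled to sum to 1; others pass through unchanged
    (idempotent). Negative probabilities are an error.
    """
    if (preds["PROB"] < 0).any():
        bad = preds.loc[preds["PROB"] < 0].iloc[0]
        raise ValueError(
            f"negative probability for gene {bad['GENE']!r} in locus {bad['LOCUS']!r}"
        )
    out = preds.copy()
    total = out.groupby("LOCUS")["PROB"].transform("sum")
    scale = np.where(total > 1.0, total, 1.0)
    out["PROB"] = out["PROB"] / scale
    return out


def build_evidence_table(
    calls: list[LocusCall],
    loci: dict[str, Locus],
    magma_meta_z: pd.Series,
    pops_pct: pd.Series,
    external: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """One evidence row per prioritized gene (heatmap-style summary).

    Columns: locus/signal ids, gene, basis, distance to the credible-set
    center in kb, PoPS percentile, meta gene z, number of genes in the
    locus, non-synonymous credible-set PIP, and one probability column per
    external prediction table (matched on locus id + gene).
    """
    rows = []
    for call in calls:
        if call.prioritized_gene is None:
            continue
        cand = call.candidates.set_index("GENE")
        g = call.prioritized_gene
        row = {
            "LOCUS": call.locus_id,
            "SIGNAL": call.signal_id,
            "GENE": g,
            "BASIS": call.basis,
            "DISTANCE_KB": cand.loc[g, "DISTANCE"] / 1_000.0,
            "POPS_PERCENTILE": pops_pct.get(g, np.nan),
            "MAGMA_META_Z": magma_meta_z.get(g, np.nan),
            "N_GENES_IN_LOCUS": len(loci[call.locus_id].genes),
            "NONSYN_PIP": cand.loc[g, "NONSYN_PIP"],
        }
        for name, preds in (external or {}).items():
            hit = preds[(preds["LOCUS"] == call.locus_id) & (preds["GENE"] == g)]
            row[name.upper()] = hit["PROB"].iloc[0] if not hit.empty else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
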