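"""Synthetic multi-ancestry GWAS scenarios with known ground truth.

Every downstream stage of the pipeline consumes only summary statistics,
an LD reference, gene models, a gene-feature matrix and a non-synonymous
variant list — so the generator produces exactly those artifacts, with
planted causal variants/genes, and nothing individual-level beyond the
reference panels themselves.

Model
-----
* Variants are laid out on ``n_chromosomes`` chromosomes at a fixed 1 kb
  spacing and grouped into LD blocks of ``ld_block_size`` adjacent variants.
* Reference haplotypes follow a per-block Markov copying chain: each allele
  is copied from the previous variant with probability ``ld_decay``, else
  redrawn from the block allele frequency. With a constant frequency per
  block this gives corr(i, j) = ld_decay**|i-j| exactly in expectation.
* Block allele frequencies diverge across ancestries via a
  Balding–Nichols beta perturbation around a shared ancestral frequency
  (fixation index ``fst``).
* Summary statistics are drawn from the standard multivariate-normal
  summary-statistics model per block: z ~ N(R @ (sqrt(n_eff) * b), R) with
  R the empirical panel correlation and b the standardized joint effects.
* Causal variants sit at the center of their causal gene; causal genes
  share a designated set of signature feature columns that are shifted by
  ``feature_signal_strength`` in the genes x features matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import BIM_COLUMNS, LDPanel

logger = logging.getLogger(__name__)

#: fixed physical spacing between adjacent simulated variants (bp)
VARIANT_SPACING = 1_000

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("G", "T"),
    ("C", "A"), ("C", "T"), ("T", "G"), ("T", "C"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class Ancestry:
    """One GWAS population: label, reference-panel size, effective N."""

    label: str
    n_ref: int
    n_eff: float


@dataclass
class SimConfig:
    """Scenario parameters; defaults are the full desk-scale study design."""

    n_variants: int = 50_000
    n_genes: int = 1_000
    n_chromosomes: int = 20
    n_features: int = 500
    n_causal_loci: int = 25
    ancestries: tuple[Ancestry, ...] = (
        Ancestry("EAS", 538, 15_886.0),
        Ancestry("EUR", 2_000, 127_626.0),
    )
    ld_block_size: int = 50
    ld_decay: float = 0.9
    causal_effect_sd: float = 0.04
    frac_nonsyn_causal: float = 0.3
    frac_nonsyn_background: float = 0.02
    feature_signal_strength: float = 2.0
    fst: float = 0.05
    freq_noise_sd: float = 0.005
    frac_palindromic: float = 0.0
    causal_min_separation_bp: int = 1_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_variants", "n_genes", "n_chromosomes", "n_features",
                     "n_causal_loci", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes (leave-one-chromosome-out)")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        for name in ("frac_nonsyn_causal", "frac_nonsyn_background",
                     "frac_palindromic"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for anc in self.ancestries:
            if anc.n_ref <= 0 or anc.n_eff <= 0:
                raise ValueError("reference and effective sample sizes must be positive")

    def ancestry(self, label: str) -> Ancestry:
        for anc in self.ancestries:
            if anc.label == label:
                return anc
        raise KeyError(f"unknown ancestry {label!r}")

    def ancestry_index(self, label: str) -> int:
        return [a.label for a in self.ancestries].index(label)


@dataclass(frozen=True)
class CausalVariant:
    snp: str
    gene: str
    beta_std: float  # effect per SD of standardized genotype, shared across ancestries
    nonsyn: bool


@dataclass
class GroundTruth:
    """Planted causal structure of a scenario."""

    causal_variants: list[CausalVariant]
    causal_genes: list[str]
    signature_features: np.ndarray  # feature columns boosted in causal genes

    def __post_init__(self) -> None:
        genes_with_variant = {cv.gene for cv in self.causal_variants}
        if set(self.causal_genes) != genes_with_variant:
            raise ValueError("every causal gene needs >=1 causal variant and vice versa")

    def beta_std_vector(self, snps: pd.Series | np.ndarray) -> np.ndarray:
        effects = {cv.snp: cv.beta_std for cv in self.causal_variants}
        return np.array([effects.get(s, 0.0) for s in np.asarray(snps)])

    def gene_of(self, snp: str) -> str | None:
        for cv in self.causal_variants:
            if cv.snp == snp:
                return cv.gene
        return None


# ---------------------------------------------------------------------------
# layout


def _chromosome_sizes(config: SimConfig) -> np.ndarray:
    base, extra = divmod(config.n_variants, config.n_chromosomes)
    return np.array([base + (1 if i < extra else 0) for i in range(config.n_chromosomes)])


def variant_map(config: SimConfig) -> pd.DataFrame:
    """``.bim``-like variant table plus a BLOCK column (internal)."""
    sizes = _chromosome_sizes(config)
    if config.ld_block_size > sizes.min():
        raise ValueError(
            f"ld_block_size {config.ld_block_size} exceeds the smallest "
            f"per-chromosome variant count {sizes.min()}"
        )
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), sizes)
    pos = np.concatenate([(np.arange(n) + 1) * VARIANT_SPACING for n in sizes])
    within = np.concatenate([np.arange(n) for n in sizes])
    block_in_chrom = within // config.ld_block_size
    # globally unique block ids
    offsets = np.concatenate(
        [[0], np.cumsum(np.ceil(sizes / config.ld_block_size).astype(int))[:-1]]
    )
    block = block_in_chrom + np.repeat(offsets, sizes)
    snp = np.array([f"rs{i + 1}" for i in range(config.n_variants)])

    rng = np.random.default_rng([config.seed, 901])
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_variants)
    alleles = np.array(_ALLELE_PAIRS)[pair_idx]
    if config.frac_palindromic > 0:
        pal = rng.random(config.n_variants) < config.frac_palindromic
        pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=config.n_variants)
        alleles[pal] = np.array(_PALINDROMIC_PAIRS)[pal_idx[pal]]

    return pd.DataFrame(
        {
            "CHR": chrom,
            "SNP": snp,
            "CM": 0.0,
            "POS": pos,
            "A1": alleles[:, 0],
            "A2": alleles[:, 1],
            "BLOCK": block,
        }
    )


def gene_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene models tiling each chromosome.

    Each chromosome is cut into equal slots; the gene body occupies the
    central 60% of its slot, leaving intergenic gaps. Coordinates are
    1-based inclusive.
    """
    sizes = _chromosome_sizes(config)
    base, extra = divmod(config.n_genes, config.n_chromosomes)
    rows = []
    gid = 0
    for c in range(config.n_chromosomes):
        n_genes_c = base + (1 if c < extra else 0)
        chrom_len = sizes[c] * VARIANT_SPACING
        slot = chrom_len / max(n_genes_c, 1)
        for g in range(n_genes_c):
            gid += 1
            start = int(g * slot + 0.2 * slot) + 1
            end = int(g * slot + 0.8 * slot)
            rows.append((f"G{gid:04d}", f"G{gid:04d}", c + 1, start, end))
    return pd.DataFrame(rows, columns=["GENE", "SYMBOL", "CHR", "START", "END"])


# ---------------------------------------------------------------------------
# allele frequencies


def _block_freqs(config: SimConfig) -> pd.DataFrame:
    """Ancestral and per-ancestry allele frequency per LD block."""
    vm = variant_map(config)
    blocks = np.unique(vm["BLOCK"])
    rng = np.random.default_rng([config.seed, 902])
    ancestral = rng.uniform(0.05, 0.95, size=len(blocks))
    out = pd.DataFrame({"BLOCK": blocks, "ANCESTRAL": ancestral})
    f = config.fst
    a_shape = ancestral * (1 - f) / f
    b_shape = (1 - ancestral) * (1 - f) / f
    for i, anc in enumerate(config.ancestries):
        rng_a = np.random.default_rng([config.seed, 903, i])
        out[anc.label] = np.clip(rng_a.beta(a_shape, b_shape), 0.02, 0.98)
    return out


# ---------------------------------------------------------------------------
# operations


def simulate_ld_panel(config: SimConfig, ancestry: str) -> LDPanel:
    """Simulate a reference genotype panel for one ancestry.

    Haplotypes are per-block Markov copying chains, so within a block
    corr(i, j) ~= ld_decay**|i-j|; blocks are independent. Deterministic
    under a fixed ``config.seed``.
    """
    anc = config.ancestry(ancestry)
    anc_idx = config.ancestry_index(ancestry)
    vm = variant_map(config)
    freqs = _block_freqs(config).set_index("BLOCK")[anc.label]
    rng = np.random.default_rng([config.seed, 904, anc_idx])

    n_hap = 2 * anc.n_ref
    geno = np.empty((anc.n_ref, config.n_variants), dtype=np.int8)
    t = config.ld_decay
    for block_id, idx in vm.groupby("BLOCK").indices.items():
        f = freqs.loc[block_id]
        m = len(idx)
        hap = np.empty((n_hap, m), dtype=bool)
        hap[:, 0] = rng.random(n_hap) < f
        for j in range(1, m):
            copy = rng.random(n_hap) < t
            fresh = rng.random(n_hap) < f
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        # note: bool + bool is logical OR in numpy; cast before summing
        geno[:, idx] = hap[: anc.n_ref].astype(np.int8) + hap[anc.n_ref:].astype(np.int8)
    return LDPanel(ancestry, geno, vm[BIM_COLUMNS + ["BLOCK"]].copy())


def build_ground_truth(config: SimConfig) -> GroundTruth:
    """Plant causal genes (well separated), causal variants and signatures."""
    genes = gene_table(config)
    rng = np.random.default_rng([config.seed, 905])
    order = rng.permutation(len(genes))
    chosen: list[int] = []
    for i in order:
        row = genes.iloc[i]
        ok = all(
            genes.iloc[j]["CHR"] != row["CHR"]
            or abs(genes.iloc[j]["START"] - row["START"]) >= config.causal_min_separation_bp
            for j in chosen
        )
        if ok:
            chosen.append(i)
        if len(chosen) == config.n_causal_loci:
            break
    if len(chosen) < config.n_causal_loci:
        raise ValueError(
            f"could only place {len(chosen)} of {config.n_causal_loci} causal loci "
            f"at separation {config.causal_min_separation_bp} bp"
        )

    vm = variant_map(config)
    causal: list[CausalVariant] = []
    n_nonsyn = int(round(config.frac_nonsyn_causal * len(chosen)))
    nonsyn_flags = np.zeros(len(chosen), dtype=bool)
    nonsyn_flags[: n_nonsyn] = True
    rng.shuffle(nonsyn_flags)
    for flag, i in zip(nonsyn_flags, chosen):
        row = genes.iloc[i]
        inside = vm[
            (vm["CHR"] == row["CHR"])
            & (vm["POS"] >= row["START"])
            & (vm["POS"] <= row["END"])
        ]
        if inside.empty:
            raise ValueError(f"gene {row['GENE']} contains no variants")
        mid = (row["START"] + row["END"]) / 2
        snp = inside.iloc[(inside["POS"] - mid).abs().argmin()]["SNP"]
        beta = rng.normal(0.0, config.causal_effect_sd)
        causal.append(CausalVariant(snp, row["GENE"], beta, bool(flag)))

    n_sig = max(5, config.n_features // 50)
    sig = np.random.default_rng([config.seed, 906]).choice(
        config.n_features, size=n_sig, replace=False
    )
    sig.sort()
    return GroundTruth(causal, [cv.gene for cv in causal], sig)


def nonsyn_table(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Non-synonymous annotation list (SNP, GENE): causal nonsyn variants
    plus a random background of in-gene variants."""
    vm = variant_map(config)
    genes = gene_table(config)
    rng = np.random.default_rng([config.seed, 909])
    rows: list[tuple[str, str]] = []
    for _, g in genes.iterrows():
        inside = vm[
            (vm["CHR"] == g["CHR"])
            & (vm["POS"] >= g["START"])
            & (vm["POS"] <= g["END"])
        ]
        take = rng.random(len(inside)) < config.frac_nonsyn_background
        rows.extend((s, g["GENE"]) for s in inside["SNP"][take])
    for cv in truth.causal_variants:
        if cv.nonsyn:
            rows.append((cv.snp, cv.gene))
    out = pd.DataFrame(rows, columns=["SNP", "GENE"]).drop_duplicates()
    return out.reset_index(drop=True)


def simulate_sumstats(
    panel: LDPanel,
    truth: GroundTruth,
    n_eff: float,
    seed,
) -> pd.DataFrame:
    """Draw GWAS summary statistics from the MVN summary-statistics model.

    Per LD block, z ~ N(R @ (sqrt(n_eff) * b), R) with R the empirical
    panel correlation and b the standardized joint effects; then
    SE = 1/sqrt(n_eff * 2 f (1-f)), beta = z * SE, two-sided normal p.
    Monomorphic panel variants are excluded (logged).
    """
    vm = panel.variants
    f = panel.freqs()
    mono = (f <= 0.0) | (f >= 1.0)
    if mono.any():
        logger.info("excluding %d monomorphic variants from summary statistics",
                    int(mono.sum()))
    b = truth.beta_std_vector(vm["SNP"])
    rng = np.random.default_rng(seed)

    z = np.empty(len(vm))
    if "BLOCK" not in vm.columns:
        raise ValueError("panel variant map lacks BLOCK structure")
    for _, idx in vm.groupby("BLOCK").indices.items():
        r = panel.corr(idx)
        mean = r @ (np.sqrt(n_eff) * b[idx])
        noise = np.linalg.cholesky(r + 1e-6 * np.eye(len(idx))) @ rng.standard_normal(len(idx))
        z[idx] = mean + noise

    keep = ~mono
    fk = np.clip(f[keep], 1e-3, 1 - 1e-3)
    se = 1.0 / np.sqrt(n_eff * 2.0 * fk * (1.0 - fk))
    zk = z[keep]
    freq_rep = np.clip(f[keep], 1e-4, 1 - 1e-4)
    out = pd.DataFrame(
        {
            "CHR": vm["CHR"].to_numpy()[keep],
            "POS": vm["POS"].to_numpy()[keep],
            "SNP": vm["SNP"].to_numpy()[keep],
            "A1": vm["A1"].to_numpy()[keep],
            "A2": vm["A2"].to_numpy()[keep],
            "FREQ": freq_rep,
            "BETA": zk * se,
            "SE": se,
            "P": np.clip(2.0 * stats.norm.sf(np.abs(zk)), 1e-300, 1.0),
            "N_EFF": float(n_eff),
        }
    )
    return out.reset_index(drop=True)


def simulate_features(
    truth: GroundTruth,
    config: SimConfig,
    seed=None,
) -> pd.DataFrame:
    """Genes x features matrix: N(0,1) background, signature columns of
    causal genes shifted by ``feature_signal_strength``."""
    genes = gene_table(config)
    rng = np.random.default_rng([config.seed if seed is None else seed, 907])
    x = rng.standard_normal((len(genes), config.n_features))
    causal_rows = genes["GENE"].isin(truth.causal_genes).to_numpy()
    x[np.ix_(causal_rows, truth.signature_features)] += config.feature_signal_strength
    return pd.DataFrame(
        x, index=genes["GENE"], columns=[f"F{j}" for j in range(config.n_features)]
    )


@dataclass
class Scenario:
    """A full simulated study: panels, summary stats, annotation, truth."""

    config: SimConfig
    truth: GroundTruth
    panels: dict[str, LDPanel]
    sumstats: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    features: pd.DataFrame
    nonsyn: pd.DataFrame


def simulate_scenario(config: SimConfig) -> Scenario:
    """Generate the complete multi-ancestry study for a config."""
    truth = build_ground_truth(config)
    panels: dict[str, LDPanel] = {}
    sumstats: dict[str, pd.DataFrame] = {}
    for i, anc in enumerate(config.ancestries):
        panel = simulate_ld_panel(config, anc.label)
        panels[anc.label] = panel
        ss = simulate_sumstats(panel, truth, anc.n_eff, seed=[config.seed, 908, i])
        if config.freq_noise_sd > 0:
            rng = np.random.default_rng([config.seed, 910, i])
            ss["FREQ"] = np.clip(
                ss["FREQ"] + rng.normal(0.0, config.freq_noise_sd, size=len(ss)),
                1e-4, 1 - 1e-4,
            )
        sumstats[anc.label] = ss
    return Scenario(
        config=config,
        truth=truth,
        panels=panels,
        sumstats=sumstats,
        genes=gene_table(config),
        features=simulate_features(truth, config),
        nonsyn=nonsyn_table(config, truth),
    )
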