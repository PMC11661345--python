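"""Linkage-disequilibrium reference panels.

An :class:`LDPanel` holds hard-call genotypes (dosage of the A1 allele,
0/1/2) for one reference population together with a PLINK ``.bim``-style
variant map. All LD quantities downstream (clumping r², COJO correlation
matrices, gene-test eigenvalues) are empirical correlations computed from
these genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of the ``.bim``-like variant map
BIM_COLUMNS = ["CHR", "SNP", "CM", "POS", "A1", "A2"]


@dataclass
class LDPanel:
    """Reference genotypes for one ancestry (or an ancestry mixture).

    Parameters
    ----------
    ancestry:
        Population label, e.g. ``"EAS"``, ``"EUR"`` or ``"MIX"``.
    genotypes:
        ``(n_samples, n_variants)`` array counting copies of the A1 allele.
    variants:
        Variant map with columns :data:`BIM_COLUMNS` (1-based positions).
    """

    ancestry: str
    genotypes: np.ndarray
    variants: pd.DataFrame
    _freqs: np.ndarray | None = field(default=None, repr=False, compare=False)
    _index: pd.Index | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (samples x variants) array")
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError(
                f"genotype columns ({self.genotypes.shape[1]}) do not match "
                f"variant map rows ({len(self.variants)})"
            )
        missing = [c for c in BIM_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant map lacks columns {missing}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def freqs(self) -> np.ndarray:
        """Empirical A1 allele frequency per variant."""
        if self._freqs is None:
            self._freqs = self.genotypes.mean(axis=0) / 2.0
        return self._freqs

    def index_of(self, snps) -> np.ndarray:
        """Column indices for the given SNP ids (KeyError if absent)."""
        if self._index is None:
            self._index = pd.Index(self.variants["SNP"])
        idx = self._index.get_indexer(np.asarray(snps))
        if (idx < 0).any():
            bad = np.asarray(snps)[idx < 0][0]
            raise KeyError(f"variant {bad!r} not in panel {self.ancestry}")
        return idx

    def standardized(self, idx=None) -> np.ndarray:
        """Column-standardized genotype matrix (mean 0, unit variance).

        Monomorphic columns are returned as all-zero so they contribute
        r = 0 rather than NaN.
        """
        g = self.genotypes if idx is None else self.genotypes[:, np.asarray(idx)]
        g = g.astype(np.float64)
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        x = (g - mu) / sd_safe
        x[:, sd == 0] = 0.0
        return x

    def corr(self, idx) -> np.ndarray:
        """Empirical correlation matrix among the given variant columns."""
        x = self.standardized(idx)
        r = (x.T @ x) / self.n_samples
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    def r_with(self, i: int, idx) -> np.ndarray:
        """Correlation of variant column ``i`` with each column in ``idx``."""
        xi = self.standardized([i])[:, 0]
        x = self.standardized(idx)
        return np.clip(x.T @ xi / self.n_samples, -1.0, 1.0)

    def subset_samples(self, rows) -> "LDPanel":
        return LDPanel(self.ancestry, self.genotypes[np.asarray(rows)], self.variants)


def combine_panels(
    panels: list[LDPanel],
    n_effs: list[float],
    label: str = "MIX",
) -> LDPanel:
    """Stack per-ancestry panels in proportion to GWAS effective sample sizes.

    The target share of each ancestry is ``n_eff_i / sum(n_eff)``. Panels are
    subsampled (first rows; reference samples are exchangeable) so the mixture
    matches those shares as closely as the available samples allow, using all
    samples of the most limiting ancestry.
    """
    if len(panels) != len(n_effs):
        raise ValueError("panels and n_effs must align")
    base = panels[0].variants["SNP"]
    for p in panels[1:]:
        if not base.equals(p.variants["SNP"]):
            raise ValueError("panels must share an identical variant map")
    shares = np.asarray(n_effs, dtype=float)
    shares = shares / shares.sum()
    avail = np.array([p.n_samples for p in panels], dtype=float)
    total = np.floor((avail / shares).min())
    counts = np.maximum(np.round(shares * total).astype(int), 1)
    geno = np.vstack([p.genotypes[: c] for p, c in zip(panels, counts)])
    return LDPanel(label, geno, panels[0].variants.copy())
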