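"""Clumping, stepwise conditional/joint selection, and signal isolation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popsloci.signal_isolation import (
    Region,
    clump,
    cojo_select,
    joint_estimates,
    leave_one_out_condition,
)
from conftest import correlated_genotypes, make_panel


def sumstats_from_z(panel, z, n_eff=50_000.0):
    """Summary-statistics table consistent with a panel and given z-scores."""
    f = np.clip(panel.freqs(), 1e-3, 1 - 1e-3)
    se = 1.0 / np.sqrt(n_eff * 2 * f * (1 - f))
    vm = panel.variants
    return pd.DataFrame(
        {
            "CHR": vm["CHR"], "POS": vm["POS"], "SNP": vm["SNP"],
            "A1": vm["A1"], "A2": vm["A2"], "FREQ": f,
            "BETA": z * se, "SE": se,
            "P": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
            "N_EFF": n_eff,
        }
    )


def consistent_z(panel, causal: dict[int, float], rng) -> np.ndarray:
    """z-scores drawn from N(R @ nc, R) with R the empirical panel LD.

    ``causal`` maps variant column -> non-centrality. Keeps marginal and
    conditional statistics mutually consistent, as in real GWAS data.
    """
    r = panel.corr(np.arange(panel.n_variants))
    nc = np.zeros(panel.n_variants)
    for i, v in causal.items():
        nc[i] = v
    chol = np.linalg.cholesky(r + 1e-6 * np.eye(len(nc)))
    return r @ nc + chol @ rng.standard_normal(len(nc))


def brute_force_clump(meta, panel, p_thresh, r2_thresh, window_bp):
    """Independent greedy reimplementation over the significant pool."""
    sig = meta[meta["P"] < p_thresh].sort_values(["P", "CHR", "POS"])
    remaining = list(sig.index)
    clumps = []
    while remaining:
        head = remaining[0]
        members = []
        for j in list(remaining):
            if sig.loc[j, "CHR"] != sig.loc[head, "CHR"]:
                continue
            if abs(sig.loc[j, "POS"] - sig.loc[head, "POS"]) > window_bp:
                continue
            gi = panel.index_of([sig.loc[head, "SNP"]])[0]
            gj = panel.index_of([sig.loc[j, "SNP"]])[0]
            r = np.corrcoef(panel.genotypes[:, gi].astype(float),
                            panel.genotypes[:, gj].astype(float))[0, 1]
            if r ** 2 >= r2_thresh:
                members.append(j)
        for j in members:
            remaining.remove(j)
        clumps.append((sig.loc[head, "SNP"], sorted(sig.loc[members, "SNP"])))
    return clumps


class TestClump:
    def test_no_significant_variants_gives_empty_list(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.integers(0, 3, (100, 10)).astype(np.int8))
        meta = sumstats_from_z(panel, rng.standard_normal(10))
        assert clump(meta, panel) == []

    def test_distant_uncorrelated_hits_form_two_regions(self):
        rng = np.random.default_rng(1)
        panel = make_panel(
            rng.integers(0, 3, (500, 2)).astype(np.int8),
            positions=np.array([1_000_000, 5_000_000]),
        )
        meta = sumstats_from_z(panel, np.array([7.0, 7.5]))
        regions = clump(meta, panel)
        assert len(regions) == 2
        assert all(len(r.index_variants) == 1 for r in regions)

    def test_correlated_cluster_forms_one_region_with_one_index(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, (800, 1)).astype(np.int8)
        cols = [base]
        for _ in range(4):  # noisy copies: pairwise r^2 well above 0.1
            c = base.copy()
            flip = rng.random((800, 1)) < 0.1
            c[flip] = rng.integers(0, 3, int(flip.sum())).astype(np.int8)
            cols.append(c)
        panel = make_panel(np.hstack(cols))
        meta = sumstats_from_z(panel, np.array([7.0, 6.5, 6.8, 6.2, 6.9]))
        regions = clump(meta, panel)
        assert len(regions) == 1
        assert regions[0].index_variants == ["rs1"]

    def test_matches_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(3)
        m = 200
        rho = 0.8 ** np.abs(np.subtract.outer(np.arange(20), np.arange(20)))
        blocks = [correlated_genotypes(rng, 1_500, rho) for _ in range(10)]
        panel = make_panel(np.hstack(blocks), positions=(np.arange(m) + 1) * 40_000)
        z = rng.standard_normal(m) * 3
        z[rng.choice(m, 15, replace=False)] += rng.choice([-8, 8], 15)
        meta = sumstats_from_z(panel, z)
        regions = clump(meta, panel, pad_bp=0, window_bp=1_000_000)
        oracle = brute_force_clump(meta, panel, 5e-8, 0.1, 1_000_000)
        got = sorted(iv for r in regions for iv in r.index_variants)
        expected = sorted(c[0] for c in oracle)
        assert got == expected

    def test_padding_and_merging(self):
        rng = np.random.default_rng(4)
        panel = make_panel(
            rng.integers(0, 3, (500, 2)).astype(np.int8),
            positions=np.array([1_000_000, 1_800_000]),
        )
        meta = sumstats_from_z(panel, np.array([7.0, 7.5]))
        regions = clump(meta, panel, pad_bp=500_000)
        # spans [500k,1.5M] and [1.3M,2.3M] overlap -> one merged region
        assert len(regions) == 1
        assert regions[0].start == 500_000 and regions[0].end == 2_300_000
        assert set(regions[0].index_variants) == {"rs1", "rs2"}

    def test_region_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            Region(1, 10, 5, [])


class TestJointEstimates:
    def test_two_variant_linear_algebra_oracle(self):
        # R^{-1} (5,4) with r=0.5 is exactly (4, 2)
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        n = np.array([1e4, 1e4])
        b, se, zj, pj = joint_estimates(np.array([5.0, 4.0]), r, n)
        np.testing.assert_allclose(b * np.sqrt(n), [4.0, 2.0])
        # se_j = sqrt((R^{-1})_jj / n); diag of R^{-1} = 1/(1-r^2)
        np.testing.assert_allclose(se, np.sqrt((1 / 0.75) / 1e4))
        np.testing.assert_allclose(zj, [4.0 * np.sqrt(0.75), 2.0 * np.sqrt(0.75)])

    def test_identity_ld_reduces_to_marginals(self):
        z = np.array([3.0, -4.0, 5.0])
        n = np.array([1e4, 2e4, 3e4])
        b, se, zj, pj = joint_estimates(z, np.eye(3), n)
        np.testing.assert_allclose(zj, z)
        np.testing.assert_allclose(b, z / np.sqrt(n))

    def test_singular_ld_raises(self):
        r = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError):
            joint_estimates(np.array([5.0, 5.0]), r, np.array([1e4, 1e4]))


class TestCojoSelect:
    def test_single_causal_gives_one_hit_with_marginal_stats(self):
        rng = np.random.default_rng(5)
        R = 0.9 ** np.abs(np.subtract.outer(np.arange(40), np.arange(40)))
        geno = np.hstack([correlated_genotypes(rng, 2_000, R) for _ in range(2)])
        panel = make_panel(geno)
        z = consistent_z(panel, {20: 9.0}, rng)
        meta = sumstats_from_z(panel, z)
        region = Region(1, 1, 80_000, [])
        hits = cojo_select(region, meta, panel)
        assert len(hits) == 1
        h = hits[0]
        assert h.snp == "rs21"
        # single-hit joint stats equal marginals (R = [1])
        assert h.joint_beta == pytest.approx(h.beta_marginal, rel=1e-6)
        assert h.joint_se == pytest.approx(h.se_marginal, rel=1e-6)

    def test_perfectly_collinear_duplicate_never_enters(self):
        rng = np.random.default_rng(6)
        base = rng.integers(0, 3, (2_000, 1)).astype(np.int8)
        other = rng.integers(0, 3, (2_000, 1)).astype(np.int8)
        panel = make_panel(np.hstack([base, base, other]))
        meta = sumstats_from_z(panel, np.array([9.0, 9.0, 1.0]))
        region = Region(1, 1, 10_000, [])
        hits = cojo_select(region, meta, panel)
        assert [h.snp for h in hits] == ["rs1"]

    def test_two_independent_causals_both_selected(self):
        rng = np.random.default_rng(7)
        R = 0.9 ** np.abs(np.subtract.outer(np.arange(40), np.arange(40)))
        geno = np.hstack([correlated_genotypes(rng, 2_000, R) for _ in range(2)])
        panel = make_panel(geno)
        z = consistent_z(panel, {10: 9.0, 60: 8.0}, rng)
        meta = sumstats_from_z(panel, z)
        region = Region(1, 1, 80_000, [])
        hits = cojo_select(region, meta, panel)
        assert len(hits) == 2
        assert {h.snp for h in hits} == {"rs11", "rs61"}
        assert all(h.joint_p < 5e-8 for h in hits)


class TestLeaveOneOut:
    def test_single_hit_conditional_equals_marginal(self):
        rng = np.random.default_rng(8)
        R = 0.9 ** np.abs(np.subtract.outer(np.arange(40), np.arange(40)))
        panel = make_panel(correlated_genotypes(rng, 2_000, R))
        z = consistent_z(panel, {5: 9.0}, rng)
        meta = sumstats_from_z(panel, z)
        region = Region(1, 1, 40_000, [])
        hits = cojo_select(region, meta, panel)
        signals = leave_one_out_condition(region, hits, meta, panel)
        assert len(signals) == 1
        pd.testing.assert_frame_equal(
            signals[0].conditional_stats, meta.reset_index(drop=True)
        )

    def test_orthogonal_hits_keep_marginals_in_their_own_block(self):
        rng = np.random.default_rng(9)
        block = 30
        R = 0.9 ** np.abs(np.subtract.outer(np.arange(block), np.arange(block)))
        geno = np.hstack([correlated_genotypes(rng, 4_000, R) for _ in range(2)])
        panel = make_panel(geno)
        z = consistent_z(panel, {5: 9.0, 45: 9.0}, rng)
        meta = sumstats_from_z(panel, z)
        region = Region(1, 1, 60_000, [])
        hits = cojo_select(region, meta, panel)
        assert len(hits) == 2
        signals = leave_one_out_condition(region, hits, meta, panel)
        for sig in signals:
            own_block = slice(0, 30) if sig.lead == "rs6" else slice(30, 60)
            z_cond = (sig.conditional_stats["BETA"] / sig.conditional_stats["SE"])
            z_marg = meta["BETA"] / meta["SE"]
            # between-block r ~ 0 in the panel, so conditioning barely moves z
            np.testing.assert_allclose(
                z_cond[own_block], z_marg[own_block], atol=0.35
            )

    def test_matches_mvn_conditioning_oracle(self):
        rng = np.random.default_rng(10)
        R = 0.85 ** np.abs(np.subtract.outer(np.arange(25), np.arange(25)))
        panel = make_panel(correlated_genotypes(rng, 3_000, R))
        z = consistent_z(panel, {4: 9.0, 18: 8.0}, rng)
        meta = sumstats_from_z(panel, z)
        region = Region(1, 1, 25_000, [])
        hits = cojo_select(region, meta, panel)
        assume_two = len(hits) == 2
        assert assume_two
        signals = leave_one_out_condition(region, hits, meta, panel)
        R_emp = panel.corr(np.arange(25))
        for sig in signals:
            other = next(h for h in hits if h.snp != sig.lead)
            c = int(other.snp[2:]) - 1
            z_cond = (sig.conditional_stats["BETA"] / sig.conditional_stats["SE"]).to_numpy()
            for v in range(25):  # brute-force per-variant MVN conditional
                if v == c:
                    assert z_cond[v] == 0.0
                    continue
                num = z[v] - R_emp[v, c] * z[c] / R_emp[c, c]
                den = np.sqrt(1 - R_emp[v, c] ** 2 / R_emp[c, c])
                np.testing.assert_allclose(z_cond[v], num / den, atol=1e-8)

    def test_self_conditioning_p_is_one(self):
        rng = np.random.default_rng(11)
        R = 0.9 ** np.abs(np.subtract.outer(np.arange(40), np.arange(40)))
        geno = np.hstack([correlated_genotypes(rng, 2_500, R) for _ in range(2)])
        panel = make_panel(geno)
        z = consistent_z(panel, {8: 9.0, 55: 9.0}, rng)
        meta = sumstats_from_z(panel, z)
        region = Region(1, 1, 80_000, [])
        hits = cojo_select(region, meta, panel)
        signals = leave_one_out_condition(region, hits, meta, panel)
        for sig in signals:
            cond = sig.conditional_stats.set_index("SNP")
            for h in hits:
                if h.snp != sig.lead:
                    assert cond.loc[h.snp, "P"] == pytest.approx(1.0)

    def test_requires_at_least_one_hit(self):
        with pytest.raises(ValueError):
            leave_one_out_condition(Region(1, 1, 10, []), [], pd.DataFrame(), None)
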