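"""Mixed-model scan: kinship arithmetic, likelihood fits, scan invariants."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, kstest

import riqtl
from riqtl.errors import DegenerateInputError, DomainError, EmptyScanError, InputError
from riqtl.lmm import (
    KinshipMatrix,
    compute_kinship,
    fit_null,
    lod_from_lrs,
    lrs_from_lod,
    scan_trait,
)
from riqtl.simulate import SimConfig, simulate_genotypes


def _zero_kinship(strain_ids):
    n = len(strain_ids)
    return KinshipMatrix(list(strain_ids), np.zeros((n, n)))


# ---------------------------------------------------------------------------
# LOD/LRS conversion
# ---------------------------------------------------------------------------

class TestLodConversion:
    def test_values(self):
        assert lod_from_lrs(0.0) == 0.0
        assert lrs_from_lod(3.0) == pytest.approx(13.83)
        # printed rounded convention: LOD 3 corresponds to LRS 13.8
        assert round(lrs_from_lod(3.0), 1) == 13.8
        assert lod_from_lrs(24.26) == pytest.approx(24.26 / 4.61)

    @given(st.floats(0.0, 1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip(self, lrs):
        assert lod_from_lrs(lrs_from_lod(lod_from_lrs(lrs))) == pytest.approx(
            lrs / 4.61, abs=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            lod_from_lrs(-1.0)
        with pytest.raises(DomainError):
            lrs_from_lod(-0.5)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

class TestKinship:
    def test_hand_oracle(self, tiny_genotypes):
        """K entries match a brute-force W W'/m computed with explicit loops."""
        K = compute_kinship(tiny_genotypes).values
        num = {"B": 0.0, "D": 1.0}
        calls = tiny_genotypes.calls
        n, m = calls.shape
        W = np.array([[num[c] for c in row] for row in calls])
        for j in range(m):
            W[:, j] -= sum(W[i, j] for i in range(n)) / n
        expected = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                expected[a, b] = sum(W[a, j] * W[b, j] for j in range(m)) / m
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_identical_strains_share_entries(self):
        calls = np.array([["B", "D", "B"], ["B", "D", "B"], ["D", "B", "D"]], "<U1")
        geno = riqtl.io.GenotypeMatrix(
            ["a", "b", "c"], ["m1", "m2", "m3"],
            np.array(["1", "1", "1"]), np.array([1.0, 2.0, 3.0]), calls,
        )
        K = compute_kinship(geno).values
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 0] == pytest.approx(K[1, 1])

    def test_constant_marker_is_inert(self, tiny_genotypes):
        """A monomorphic marker centers to zero and cannot change W W'."""
        g = tiny_genotypes
        aug = riqtl.io.GenotypeMatrix(
            g.strain_ids,
            g.marker_ids + ["mono"],
            np.append(g.chromosome, "2"),
            np.append(g.position_mb, 99.0),
            np.hstack([g.calls, np.full((4, 1), "B", "<U1")]),
        )
        K3 = compute_kinship(tiny_genotypes).values * 3  # un-normalize
        K4 = compute_kinship(aug).values * 4
        np.testing.assert_allclose(K3, K4, atol=1e-12)

    def test_loco_excludes_chromosome(self, tiny_genotypes):
        K = compute_kinship(tiny_genotypes, exclude_chromosome="2")
        assert K.excluded_chromosome == "2"
        # only markers m1, m2 (chromosome 1) contribute
        num = tiny_genotypes.numeric()[:, :2]
        W = num - num.mean(axis=0)
        np.testing.assert_allclose(K.values, W @ W.T / 2, atol=1e-12)

    def test_loco_all_markers_excluded_errors(self, tiny_genotypes):
        mono = tiny_genotypes.subset_markers(tiny_genotypes.chromosome == "2")
        with pytest.raises(DegenerateInputError):
            compute_kinship(mono, exclude_chromosome="2")

    def test_simulated_kinship_psd(self, small_panel):
        assert compute_kinship(small_panel).is_psd()


# ---------------------------------------------------------------------------
# null model fit
# ---------------------------------------------------------------------------

class TestFitNull:
    def test_collapses_to_ols_with_zero_kinship(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10.0, 2.0, size=40)
        fit = fit_null(y, _zero_kinship([f"s{i}" for i in range(40)]))
        assert fit.beta_hat[0] == pytest.approx(y.mean(), rel=1e-8)
        # with K = 0 the residual variance is the ML variance estimate
        assert fit.sigma_e2 == pytest.approx(np.var(y), rel=1e-6)
        n = len(y)
        ll_ols = -0.5 * n * (np.log(2 * np.pi) + 1 + np.log(np.var(y)))
        assert fit.log_likelihood == pytest.approx(ll_ols, rel=1e-10)

    def test_constant_trait_flagged_degenerate(self):
        y = np.full(20, 7.0)
        fit = fit_null(y, _zero_kinship([f"s{i}" for i in range(20)]))
        assert fit.degenerate
        assert np.isfinite(fit.log_likelihood)

    def test_nonfinite_trait_rejected(self):
        y = np.array([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(InputError):
            fit_null(y, _zero_kinship(["a", "b", "c", "d"]))

    def test_delta_recovery_large_n(self):
        """delta = sigma_e2/sigma_g2 = 1 recovered within 20% at n=2000."""
        rng = np.random.default_rng(42)
        n, m = 2000, 400
        W = rng.standard_normal((n, m))
        K = W @ W.T / m
        s, U = np.linalg.eigh(K)
        s = np.clip(s, 0, None)
        g = U @ (np.sqrt(s) * rng.standard_normal(n))
        y = 3.0 + g + rng.standard_normal(n)
        fit = fit_null(y, KinshipMatrix([f"s{i}" for i in range(n)], K))
        assert fit.delta == pytest.approx(1.0, rel=0.20)


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def _noise_trait(geno, seed):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.standard_normal(geno.n_strains), index=geno.strain_ids)


class TestScan:
    def test_maf_filter_drops_rare_markers(self, small_panel):
        scan = scan_trait(_noise_trait(small_panel, 1), small_panel)
        assert (scan.table["maf"] >= 0.05).all()
        num = small_panel.numeric()
        p = num.mean(axis=0)
        rare = np.minimum(p, 1 - p) < 0.05 - 1e-12
        assert not set(np.asarray(small_panel.marker_ids)[rare]) & set(scan.table["marker"])

    def test_all_markers_filtered_errors(self, tiny_genotypes):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=tiny_genotypes.strain_ids)
        with pytest.warns(UserWarning):
            with pytest.raises(EmptyScanError):
                scan_trait(y, tiny_genotypes, maf_min=0.9)

    def test_lod_is_lrs_over_461(self, small_panel):
        t = scan_trait(_noise_trait(small_panel, 2), small_panel).table
        np.testing.assert_allclose(t["lod"], t["lrs"] / 4.61, rtol=1e-9)
        assert (t["lrs"] >= 0).all()
        # neg_log10_p strictly increasing in LRS
        order = np.argsort(t["lrs"].to_numpy())
        nlp = t["neg_log10_p"].to_numpy()[order]
        lrs = t["lrs"].to_numpy()[order]
        distinct = np.diff(lrs) > 1e-12
        assert (np.diff(nlp)[distinct] > 0).all()

    def test_strain_permutation_invariance(self, small_panel):
        y = _noise_trait(small_panel, 3)
        base = scan_trait(y, small_panel).table
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(small_panel.strain_ids))
        shuffled = scan_trait(y.reindex(perm), small_panel.subset_strains(perm)).table
        np.testing.assert_allclose(base["lrs"], shuffled["lrs"], atol=1e-6)

    def test_duplicate_marker_same_statistics(self, small_panel):
        g = small_panel
        j = 10  # duplicate inserted right after the original to keep Mb order
        dup = riqtl.io.GenotypeMatrix(
            g.strain_ids,
            g.marker_ids[: j + 1] + ["dup"] + g.marker_ids[j + 1 :],
            np.insert(g.chromosome, j + 1, g.chromosome[j]),
            np.insert(g.position_mb, j + 1, g.position_mb[j] + 1e-6),
            np.insert(g.calls, j + 1, g.calls[:, j], axis=1),
        )
        t = scan_trait(_noise_trait(g, 4), dup).table.set_index("marker")
        assert t.loc["dup", "lrs"] == pytest.approx(
            t.loc[g.marker_ids[j], "lrs"], abs=1e-6
        )

    def test_affine_trait_invariance(self, small_panel):
        y = _noise_trait(small_panel, 5)
        a = scan_trait(y, small_panel).table
        b = scan_trait(-2.5 * y + 7.0, small_panel).table
        np.testing.assert_allclose(a["lrs"], b["lrs"], rtol=1e-6, atol=1e-6)

    def test_zero_kinship_matches_ols_likelihood_ratio(self, small_panel):
        """With K = 0 every marker p equals the simple-regression LRT p."""
        y = _noise_trait(small_panel, 6)
        scan = scan_trait(y, small_panel, kinship=_zero_kinship(small_panel.strain_ids))
        yv = y.reindex(small_panel.strain_ids).to_numpy()
        n = len(yv)
        num = small_panel.numeric()
        cols = {m: i for i, m in enumerate(small_panel.marker_ids)}
        rss0 = ((yv - yv.mean()) ** 2).sum()
        for _, row in scan.table.iterrows():
            x = num[:, cols[row["marker"]]]
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.lstsq(X, yv, rcond=None)[0]
            rss1 = ((yv - X @ beta) ** 2).sum()
            p_ols = chi2.sf(n * np.log(rss0 / rss1), df=1)
            assert row["p"] == pytest.approx(p_ols, rel=1e-6)

    def test_null_pvalues_marginally_uniform(self):
        """Pooled null p at approximately independent markers is uniform.

        Markers within one scan share long RI LD blocks, so uniformity is
        assessed on one marker per chromosome per seed (independent draws).
        """
        vals = []
        for seed in range(20):
            cfg = SimConfig(
                n_strains=70, n_chromosomes=5, markers_per_chromosome=200,
                planted_qtls=[], heritability_polygenic=0.0, n_genes=1, seed=seed,
            )
            geno = simulate_genotypes(cfg)
            scan = scan_trait(_noise_trait(geno, seed + 1000), geno)
            t = scan.table
            for c in geno.chromosomes():
                sub = t[t["chromosome"] == c]
                vals.append(sub["p"].iloc[len(sub) // 2])
        assert kstest(np.asarray(vals), "uniform").pvalue > 0.01

    def test_few_strains_warns(self, tiny_genotypes):
        g = tiny_genotypes
        big = riqtl.io.GenotypeMatrix(
            g.strain_ids + ["s5"],
            g.marker_ids,
            g.chromosome,
            g.position_mb,
            np.vstack([g.calls, np.array([["B", "D", "B"]], "<U1")]),
        )
        y = pd.Series([1.0, 2.0, 1.5, 2.5, 1.8], index=big.strain_ids)
        with pytest.warns(UserWarning, match="strains"):
            scan_trait(y, big)
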