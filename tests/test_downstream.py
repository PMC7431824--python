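import numpy as np
import pandas as pd
import pytest

from methage.dmr_caller import DMR, DMRCallerConfig, call_dmrs
from methage.downstream import (
    cluster_dmr_cpgs,
    compare_groups,
    reanalyze_beta_matrix,
    regress_meth_on_age,
    test_probes_ttest as probe_ttest,
)
from methage.cpg_stats import test_sites_ttest as ttest_sites
from methage.meth_io import BetaMatrix, MethylationDataset

from oracles import ols_normal_equations


class TestRegression:
    def test_perfect_line(self):
        fit = regress_meth_on_age([40, 35, 30], [50, 55, 60])
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(90.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_meth_on_age([1, 2, 3], [50, 50, 50])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            regress_meth_on_age([1, 2], [50, 60])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(50, 64, size=10)
        y = 80 - 0.5 * x + rng.normal(0, 3, size=10)
        fit = regress_meth_on_age(y, x)
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_null_slope_p_is_calibrated(self):
        """Methylation independent of age: slope p-values are uniform, so
        about 5% (±2%) of 1,000 replicates reach p <= .05."""
        rng = np.random.default_rng(42)
        sig = 0
        for _ in range(1000):
            ages = rng.uniform(25, 64, size=18)
            meth = rng.normal(50, 5, size=18)
            if regress_meth_on_age(meth, ages).p_value <= 0.05:
                sig += 1
        assert 0.03 <= sig / 1000 <= 0.07


class TestCompareGroups:
    def test_identical_groups(self):
        t_p, u_p = compare_groups([10, 10, 10], [10, 10, 10])
        assert t_p == 1.0 and u_p == 1.0

    def test_fully_separated_small_groups(self):
        # exact two-sided Mann-Whitney with n=3,3: most extreme of C(6,3)=20
        _, u_p = compare_groups([1, 2, 3], [10, 11, 12])
        assert u_p == pytest.approx(0.1)

    def test_rank_test_invariant_under_monotone_transform(self):
        y, a = [1.0, 2.0, 3.5, 2.5], [4.0, 5.5, 6.0, 7.0]
        _, u1 = compare_groups(y, a)
        _, u2 = compare_groups(np.exp(y), np.exp(a))
        assert u1 == pytest.approx(u2)


def two_group_dataset(pct_rows, n_young=3, n_apa=3, reads=1000):
    """Dataset whose per-sample percentages are given exactly (reads=1000)."""
    pct = np.asarray(pct_rows, dtype=float)
    n_meth = np.round(pct * reads / 100).astype(int)
    n_unmeth = reads - n_meth
    n = pct.shape[1]
    assert n == n_young + n_apa
    return MethylationDataset(
        chrom=np.array(["chr1"] * len(pct), dtype=object),
        pos=np.arange(100, 100 + 10 * len(pct), 10),
        n_meth=n_meth,
        n_unmeth=n_unmeth,
        sample_ids=[f"s{i}" for i in range(n)],
        group=np.array(["young"] * n_young + ["APA"] * n_apa, dtype=object),
    )


class TestClustering:
    def make_inputs(self, rng, delta=30.0):
        # mixed hyper and hypo member CpGs, as called regions deliver
        base = rng.uniform(20, 60, size=(10, 1))
        sign = np.where(np.arange(10) % 2 == 0, 1.0, -1.0)[:, None]
        young = base + rng.normal(0, 3, size=(10, 6))
        apa = base + sign * delta + rng.normal(0, 3, size=(10, 6))
        pct = np.clip(np.hstack([young, apa]), 0, 100)
        ds = two_group_dataset(pct, n_young=6, n_apa=6)
        dmrs = [DMR("chr1", 100, 191, "hyper", 10, delta, tuple(ds.pos))]
        return ds, dmrs

    def test_two_cluster_cut_recovers_groups(self):
        ds, dmrs = self.make_inputs(np.random.default_rng(0))
        result = cluster_dmr_cpgs(ds, dmrs)
        labels = result.labels
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_samples_are_perfectly_correlated(self):
        rng = np.random.default_rng(1)
        base = rng.normal(50, 10, size=(5, 1))
        pct = np.hstack([base, base, base + rng.normal(0, 20, size=(5, 1)),
                         base + rng.normal(0, 20, size=(5, 1))])
        ds = two_group_dataset(np.clip(pct, 0, 100), n_young=2, n_apa=2)
        z = cluster_dmr_cpgs(
            ds, [DMR("chr1", 100, 141, "hyper", 5, 20.0, tuple(ds.pos))]
        ).z_matrix.to_numpy()
        corr = np.corrcoef(z.T)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_two_sample_distance_bound(self):
        # anti-correlated sample pair: distance hits the 1 - r bound of 2
        pct = np.array([[10.0, 90.0], [80.0, 20.0], [30.0, 70.0]])
        ds = two_group_dataset(pct, n_young=1, n_apa=1)
        z = cluster_dmr_cpgs(
            ds, [DMR("chr1", 100, 121, "hyper", 3, 60.0, tuple(ds.pos))]
        ).z_matrix.to_numpy()
        assert 1 - np.corrcoef(z.T)[0, 1] == pytest.approx(2.0)

    def test_affine_rescaling_invariance(self):
        ds, dmrs = self.make_inputs(np.random.default_rng(2))
        l1 = cluster_dmr_cpgs(ds, dmrs).labels
        # rescale each CpG row affinely (percent scale shrunk and shifted)
        pct = ds.percent() * 0.5 + 10
        ds2 = two_group_dataset(pct, n_young=6, n_apa=6)
        l2 = cluster_dmr_cpgs(ds2, dmrs).labels
        assert np.array_equal(l1, l2) or np.array_equal(l1, 3 - l2)

    def test_constant_rows_dropped_with_warning(self):
        pct = np.array([[50.0] * 6, [10, 20, 30, 60, 70, 80]])
        ds = two_group_dataset(pct, n_young=3, n_apa=3)
        with pytest.warns(UserWarning, match="constant"):
            cluster_dmr_cpgs(
                ds, [DMR("chr1", 100, 121, "hyper", 2, 40.0, tuple(ds.pos))]
            )


def beta_matrix_from(pct_rows, positions=None, n_young=3, n_apa=3, chrom="chr1"):
    beta = np.asarray(pct_rows, dtype=float) / 100.0
    n_probes = len(beta)
    pos = positions if positions is not None else np.arange(100, 100 + 10 * n_probes, 10)
    probes = pd.DataFrame(
        {"probe_id": [f"cg{i:06d}" for i in range(n_probes)],
         "chrom": chrom, "pos": pos}
    )
    return BetaMatrix(
        probes=probes,
        beta=beta,
        sample_ids=[f"s{i}" for i in range(n_young + n_apa)],
        group=np.array(["young"] * n_young + ["APA"] * n_apa, dtype=object),
    )


class TestArrayReanalysis:
    SPIKED = [
        [80, 79, 81, 50, 49, 51],
        [78, 80, 82, 48, 50, 52],
        [81, 79, 80, 51, 49, 50],
        [80, 81, 79, 50, 51, 49],
    ]
    NULL = [[60, 61, 59, 60, 61, 59]] * 3

    def test_spiked_region_called_hypo(self):
        bm = beta_matrix_from(self.SPIKED + self.NULL)
        dmrs = reanalyze_beta_matrix(bm)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hypo" and d.n_sig_cpgs == 4
        assert d.mean_delta == pytest.approx(-30.0, abs=1.0)

    def test_two_probe_cluster_needs_array_mode(self):
        bm = beta_matrix_from(self.SPIKED[:2] + self.NULL)
        assert len(reanalyze_beta_matrix(bm)) == 1
        strict = reanalyze_beta_matrix(
            bm, caller_config=DMRCallerConfig(min_cpgs=3)
        )
        assert strict == []

    def test_unlocated_probes_dropped(self):
        bm = beta_matrix_from(self.SPIKED + self.NULL)
        bm.probes.loc[len(bm.probes) - 1, ["chrom", "pos"]] = [None, np.nan]
        res = probe_ttest(bm)
        assert len(res) == len(bm.probes) - 1

    def test_null_beta_matrix_false_region_rate(self):
        """With no group difference, array-mode calling stays below one
        false region per 10,000 probes (pooled over 20 seeds)."""
        import dataclasses
        from methage.synthetic_data import (
            SimulationConfig, simulate_beta_matrix, simulate_genome,
        )

        base = SimulationConfig(
            n_chroms=2, chrom_length=2_000_000, n_islands=40,
            background_cpg_rate=2.5e-3, n_spiked_hyper=0, n_spiked_hypo=0,
        )
        false = probes = 0
        for seed in range(20):
            cfg = dataclasses.replace(base, seed=seed)
            bm, _ = simulate_beta_matrix(simulate_genome(cfg), cfg)
            false += len(reanalyze_beta_matrix(bm))
            probes += len(bm.probes)
        assert probes >= 200_000
        assert false / probes <= 1e-4

    def test_beta_and_count_paths_agree_on_noiseless_data(self):
        """Counts whose percentages equal 100*beta give identical DMRs."""
        rows = self.SPIKED + self.NULL + [[20, 21, 19, 45, 44, 46]] * 3
        positions = np.concatenate([np.arange(100, 170, 10),
                                    np.arange(5000, 5030, 10)])
        bm = beta_matrix_from(rows, positions=positions)
        ds = two_group_dataset(np.asarray(rows, dtype=float), n_young=3, n_apa=3)
        ds.pos = positions  # match probe coordinates
        cfg = DMRCallerConfig(min_cpgs=2)
        from_beta = reanalyze_beta_matrix(bm, caller_config=cfg)
        from_counts = call_dmrs(ttest_sites(ds), cfg)
        assert [
            (d.chrom, d.start, d.end, d.direction, d.n_sig_cpgs)
            for d in from_beta
        ] == [
            (d.chrom, d.start, d.end, d.direction, d.n_sig_cpgs)
            for d in from_counts
        ]
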