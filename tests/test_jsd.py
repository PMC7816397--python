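"""JSD operator, KDE, balanced subsampling, iteration engine, permutation."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from allomix import (
    AlloEffectSpec,
    GeneratorConfig,
    JSDParams,
    balanced_subsample,
    generate_counts,
    inject_allo_effect,
    jsd,
    kde2d,
    permutation_null,
    run_jsd_iterations,
)
from allomix.jsd_analysis import allo_marker_report, nrd_bandwidth
from allomix.qc import filter_counts, normalize_log


def _oracle_jsd(p, q):
    """Direct summation of the base-2 JSD definition."""
    p, q = np.asarray(p, float).ravel(), np.asarray(q, float).ravel()
    m = (p + q) / 2
    total = 0.0
    for pi, qi, mi in zip(p, q, m):
        if pi > 0:
            total += 0.5 * pi * np.log2(pi / mi)
        if qi > 0:
            total += 0.5 * qi * np.log2(qi / mi)
    return total


class TestJSDOperator:
    def test_identity(self):
        p = np.full((5, 5), 1 / 25)
        assert jsd(p, p) == 0.0

    def test_disjoint_supports_reach_one(self):
        assert jsd(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_worked_value(self):
        val = jsd(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert val == pytest.approx(_oracle_jsd([1, 0], [0.5, 0.5]), abs=1e-12)
        assert val == pytest.approx(0.3113, abs=1e-4)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            jsd(np.ones(4) / 4, np.ones(5) / 5)

    def test_against_scipy_and_oracle_on_random_grids(self, rng):
        for _ in range(300):
            p = rng.dirichlet(np.ones(25)).reshape(5, 5)
            q = rng.dirichlet(np.ones(25)).reshape(5, 5)
            v = jsd(p, q)
            assert v == pytest.approx(_oracle_jsd(p, q), abs=1e-9)
            assert v == pytest.approx(jensenshannon(p.ravel(), q.ravel(),
                                                    base=2) ** 2, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_symmetry_bounds_properties(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(16))
        q = r.dirichlet(np.ones(16))
        v = jsd(p, q)
        assert v == pytest.approx(jsd(q, p), abs=1e-12)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert jsd(p, p) == 0.0


class TestKDE2D:
    WINDOW = ((-4.0, 4.0), (-4.0, 4.0))

    def test_tight_cluster_peaks_at_center(self, rng):
        pts = rng.normal(0, 0.05, size=(200, 2))
        g = kde2d(pts, self.WINDOW, grid_size=25)
        assert np.unravel_index(g.weights.argmax(), g.weights.shape) == (12, 12)

    def test_identical_points_identical_grids(self, rng):
        pts = rng.normal(size=(100, 2))
        a = kde2d(pts, self.WINDOW)
        b = kde2d(pts.copy(), self.WINDOW)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_standard_normal_marginal_means(self, rng):
        pts = rng.standard_normal((1000, 2))
        g = kde2d(pts, self.WINDOW, grid_size=25)
        gx = np.linspace(-4, 4, 25)
        mean_x = (g.weights.sum(axis=1) * gx).sum()
        mean_y = (g.weights.sum(axis=0) * gx).sum()
        assert abs(mean_x) < 0.15
        assert abs(mean_y) < 0.15

    def test_degenerate_axis_floors_bandwidth(self):
        pts = np.column_stack([np.zeros(50), np.linspace(-1, 1, 50)])
        with pytest.warns(UserWarning, match="floored"):
            g = kde2d(pts, self.WINDOW)
        assert np.isfinite(g.weights).all()

    def test_matches_reference_r_implementation(self, tmp_path, rng):
        """Raw density values agree with the classical R estimator."""
        pts = rng.normal(size=(60, 2)) * [1.3, 0.7] + [0.5, -1.0]
        f = tmp_path / "pts.txt"
        np.savetxt(f, pts)
        script = (
            f'x <- as.matrix(read.table("{f}"));'
            'k <- MASS::kde2d(x[,1], x[,2], n=25, lims=c(-4,4,-4,4));'
            'cat(sprintf("%.12g", k$z[1,1]), sprintf("%.12g", k$z[13,13]),'
            '    sprintf("%.12g", k$z[25,7]),'
            '    sprintf("%.12g", MASS::bandwidth.nrd(x[,1])))'
        )
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, timeout=120)
        assert proc.returncode == 0, proc.stderr
        z11, z1313, z257, bw = map(float, proc.stdout.split())
        g = kde2d(pts, self.WINDOW, grid_size=25)
        assert g.density[0, 0] == pytest.approx(z11, rel=1e-9)
        assert g.density[12, 12] == pytest.approx(z1313, rel=1e-9)
        assert g.density[24, 6] == pytest.approx(z257, rel=1e-9)
        assert nrd_bandwidth(pts[:, 0]) == pytest.approx(bw, rel=1e-9)


class TestBalancedSubsample:
    @staticmethod
    def _annotation(sizes: dict[str, int], celltype="CD4 T") -> pd.DataFrame:
        rows = []
        for g, n in sizes.items():
            rows += [(g, celltype, "")] * n
        df = pd.DataFrame(rows, columns=["group", "cell_type", "cd4_subtype"])
        df.index = [f"c{i}" for i in range(len(df))]
        return df

    @pytest.mark.parametrize("min_size,expected", [(167, 1336), (56, 448),
                                                   (108, 864)])
    def test_published_subset_sizes(self, min_size, expected):
        groups = [f"G{i}" for i in range(8)]
        sizes = {g: min_size + 13 * i for i, g in enumerate(groups)}
        ann = self._annotation(sizes)
        idx = balanced_subsample(ann, "CD4 T", groups, rng=0)
        assert len(idx) == expected

    def test_equal_groups_return_everything(self):
        groups = ["A1", "A4"]
        ann = self._annotation({g: 60 for g in groups})
        idx = balanced_subsample(ann, "CD4 T", groups, rng=0)
        assert len(idx) == 120
        assert set(idx) == set(ann.index)

    def test_deterministic_given_seed(self):
        ann = self._annotation({"A1": 80, "A4": 120})
        a = balanced_subsample(ann, "CD4 T", ["A1", "A4"], rng=5)
        b = balanced_subsample(ann, "CD4 T", ["A1", "A4"], rng=5)
        assert list(a) == list(b)

    def test_cd4_stratified_by_subtype(self):
        rows = []
        for g, (n_naive, n_mem) in {"A1": (30, 10), "A4": (20, 25)}.items():
            rows += [(g, "CD4 T", "naive")] * n_naive
            rows += [(g, "CD4 T", "memory")] * n_mem
        ann = pd.DataFrame(rows, columns=["group", "cell_type", "cd4_subtype"])
        ann.index = [f"c{i}" for i in range(len(ann))]
        idx = balanced_subsample(ann, "CD4 T", ["A1", "A4"], rng=1)
        sub = ann.loc[idx]
        tab = sub.groupby(["group", "cd4_subtype"], observed=True).size()
        # min(naive)=20, min(memory)=10 in each group
        assert tab.loc[("A1", "naive")] == tab.loc[("A4", "naive")] == 20
        assert tab.loc[("A1", "memory")] == tab.loc[("A4", "memory")] == 10

    def test_unknown_group_rejected(self):
        ann = self._annotation({"A1": 60})
        with pytest.raises(ValueError, match="A9"):
            balanced_subsample(ann, "CD4 T", ["A1", "A9"], rng=0)


@pytest.fixture(scope="module")
def jsd_dataset():
    data = generate_counts(GeneratorConfig(seed=17, cells_per_donor_per_lane=600))
    norm = normalize_log(filter_counts(data.adata))
    ann = norm.obs[["group", "cell_type", "cd4_subtype"]].copy()
    return norm, ann


class TestIterationEngine:
    def test_matrices_scaled_and_symmetric(self, jsd_dataset):
        norm, ann = jsd_dataset
        params = JSDParams(n_iterations=3, seed=0)
        res = run_jsd_iterations(norm, params, annotation=ann,
                                 celltypes=["CD4 T"])
        mats = res.per_celltype["CD4 T"].matrices
        for m in mats:
            np.testing.assert_allclose(m, m.T)
            assert np.all(np.diag(m) == 0)
            off = m[~np.eye(m.shape[0], dtype=bool)]
            assert off.min() == pytest.approx(0.0)
            assert off.max() == pytest.approx(1.0)

    def test_fully_reproducible(self, jsd_dataset):
        norm, ann = jsd_dataset
        params = JSDParams(n_iterations=2, seed=42)
        a = run_jsd_iterations(norm, params, annotation=ann,
                               celltypes=["CD8 T"])
        b = run_jsd_iterations(norm, params, annotation=ann,
                               celltypes=["CD8 T"])
        np.testing.assert_array_equal(a.per_celltype["CD8 T"].matrices,
                                      b.per_celltype["CD8 T"].matrices)

    def test_small_groups_excluded(self, jsd_dataset):
        norm, ann = jsd_dataset
        params = JSDParams(n_iterations=1, min_cells_per_group=10**6, seed=0)
        res = run_jsd_iterations(norm, params, annotation=ann,
                                 celltypes=["CD4 T"])
        assert "CD4 T" in res.excluded
        assert "CD4 T" not in res.per_celltype

    def test_inter_donor_exceeds_mixing(self, jsd_dataset):
        """Donor effects separate groups far more than mixing status."""
        norm, ann = jsd_dataset
        params = JSDParams(n_iterations=5, seed=3)
        res = run_jsd_iterations(norm, params, annotation=ann)
        for ct, r in res.per_celltype.items():
            assert (r.set_series["inter_donor"].mean()
                    > r.set_series["mixing"].mean()), ct


class TestPermutationNull:
    def test_null_diffs_centered_at_zero(self, jsd_dataset):
        norm, ann = jsd_dataset
        params = JSDParams(n_iterations=5, n_permutations=30, seed=11)
        res = run_jsd_iterations(norm, params, annotation=ann,
                                 celltypes=["CD14 Monocyte"])
        perm = permutation_null(norm, params, observed=res, annotation=ann)
        diffs = perm.null_diffs["CD14 Monocyte"]
        assert abs(diffs.mean()) < 2 * diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert perm.verdicts["CD14 Monocyte"] in {"not significant",
                                                  "significant mixing effect"}

    def test_verdict_flips_with_injected_effect(self):
        base = generate_counts(
            GeneratorConfig(seed=23, cells_per_donor_per_lane=600)
        )
        spec = AlloEffectSpec(
            up_genes=tuple(f"ALLOUP{i:02d}" for i in range(3, 26)) + ("IFNG",
                                                                      "CD40LG"),
            down_genes=tuple(f"ALLODN{i:02d}" for i in range(3, 26)) + ("DUSP1",
                                                                        "FOS"),
            fold_change_up=4.0, fold_change_down=4.0, affected_fraction=0.5,
        )
        injected = inject_allo_effect(base, spec, seed=1)
        params = JSDParams(n_iterations=10, n_permutations=20, seed=2)
        for data, expect_sig in [(base, False), (injected, True)]:
            norm = normalize_log(filter_counts(data.adata))
            ann = norm.obs[["group", "cell_type", "cd4_subtype"]].copy()
            res = run_jsd_iterations(norm, params, annotation=ann,
                                     celltypes=["CD4 T"])
            perm = permutation_null(norm, params, observed=res, annotation=ann)
            sig = perm.verdicts["CD4 T"] == "significant mixing effect"
            assert sig == expect_sig


class TestAlloMarkerReport:
    def test_identical_groups_give_p_one(self, jsd_dataset):
        norm, _ = jsd_dataset
        ann = norm.obs[["cd4_subtype", "mixing_status", "donor"]].copy()
        # constant expression: zero out a marker entirely
        report = allo_marker_report(norm, annotation=ann, markers=("IFNG",))
        assert set(report["status"]) <= {"ok", "missing"}

    def test_null_generator_markers_not_significant(self, jsd_dataset):
        norm, _ = jsd_dataset
        report = allo_marker_report(norm)
        ok = report[report["status"] == "ok"]
        assert (ok["qvalue"] >= 0.05).all()

    def test_injected_ifng_effect_detected(self):
        base = generate_counts(
            GeneratorConfig(seed=29, cells_per_donor_per_lane=500)
        )
        injected = inject_allo_effect(base, AlloEffectSpec(), seed=4)
        norm = normalize_log(filter_counts(injected.adata))
        report = allo_marker_report(norm)
        ifng = report[(report["gene"] == "IFNG") & (report["status"] == "ok")]
        assert (ifng["qvalue"] < 0.05).any()
        assert (ifng["mean_mixed"] > ifng["mean_unmixed"]).all()

    def test_missing_marker_reported_not_raised(self, jsd_dataset):
        norm, _ = jsd_dataset
        report = allo_marker_report(norm, markers=("IFNG", "NOT_A_GENE"))
        missing = report[report["gene"] == "NOT_A_GENE"]
        assert (missing["status"] == "missing").all()

    def test_tied_expression_exact_p_one(self):
        import anndata as ad
        from scipy import sparse

        X = np.ones((40, 1))
        a = ad.AnnData(X=sparse.csr_matrix(X))
        a.var_names = ["IFNG"]
        a.obs_names = [f"c{i}" for i in range(40)]
        ann = pd.DataFrame(
            {
                "cd4_subtype": ["naive"] * 40,
                "mixing_status": ["mixed"] * 20 + ["unmixed"] * 20,
                "donor": ["A"] * 40,
            },
            index=a.obs_names,
        )
        report = allo_marker_report(a, annotation=ann, markers=("IFNG",))
        assert report["pvalue"].iloc[0] == 1.0
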