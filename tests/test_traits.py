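"""Diet axis, trait transforms, phylogenetic eigenvectors, RF imputation."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from predniche import synthetic, traits
from predniche.synthetic import DIET_CATEGORIES, SimConfig
from predniche.traits import (
    ImputationConfig,
    classical_scaling,
    diet_axis,
    gower_distance,
    phylo_eigenvectors,
    rf_impute,
    transform_traits,
)

DIET_COLS = [f"diet_{c}" for c in DIET_CATEGORIES]


def diet_frame(rows, index=None):
    idx = index or [f"sp{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=DIET_COLS, index=idx)


class TestDietAxis:
    def test_identical_rows_zero_gower_distance(self):
        X = np.array([[0.5, 0.5, 0, 0, 0, 0, 0], [0.5, 0.5, 0, 0, 0, 0, 0],
                      [0.1, 0.2, 0.7, 0, 0, 0, 0]])
        D = gower_distance(X)
        assert D[0, 1] == 0.0
        assert D[0, 2] > 0

    def test_specialist_clusters_get_opposite_signs(self):
        rng = np.random.default_rng(0)
        inverts = np.zeros((10, 7))
        inverts[:, 0] = 1.0  # pure invertebrate eaters
        plants = np.zeros((10, 7))
        plants[:, 5] = 1.0   # pure plant eaters
        X = np.vstack([inverts, plants]) + rng.uniform(0, 0.02, (20, 7))
        X /= X.sum(axis=1, keepdims=True)
        axis = diet_axis(diet_frame(X))
        assert (axis.scores.iloc[:10] > 0).all()
        assert (axis.scores.iloc[10:] < 0).all()

    def test_invertebrate_loading_positive(self, small_tree, small_cfg):
        truth, _ = synthetic.generate_trait_table(small_tree, small_cfg)
        axis = diet_axis(truth[DIET_COLS])
        assert axis.loadings["invertebrates"] > 0

    def test_classical_scaling_identity_on_euclidean_matrix(self):
        """Exact identity: coordinates of a Euclidean distance matrix
        reproduce it to machine precision."""
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        P = rng.normal(size=(20, 4))
        D = squareform(pdist(P))
        coords, vals = classical_scaling(D)
        D_hat = squareform(pdist(coords))
        assert np.allclose(D, D_hat, atol=1e-8)

    def test_full_rank_scores_reconstruct_gower_distances(self):
        """Retained-axis distances reproduce the Gower matrix closely; the
        small deficit is the dropped negative-eigenvalue mass (Gower is not
        exactly Euclidean), which the Cailliez correction removes."""
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        X = rng.dirichlet(np.ones(7) * 0.8, size=30)
        D = gower_distance(X)
        coords, vals = classical_scaling(D)
        D_hat = squareform(pdist(coords))
        iu = np.triu_indices(30, k=1)
        assert np.corrcoef(D[iu], D_hat[iu])[0, 1] > 0.98
        # corrected distances are Euclidean: reconstruction becomes exact
        from predniche.traits import cailliez_correction

        Dc = cailliez_correction(D)
        coords_c, _ = classical_scaling(Dc)
        Dc_hat = squareform(pdist(coords_c))
        assert np.allclose(Dc, Dc_hat, atol=1e-6)

    def test_agrees_with_skbio_pcoa(self):
        """Independent cross-check: first-axis scores match scikit-bio's
        PCoA of the same distance matrix (up to sign)."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(2)
        X = rng.dirichlet(np.ones(7), size=25)
        D = gower_distance(X)
        ours, vals = classical_scaling(D)
        theirs = pcoa(DistanceMatrix(D)).samples.iloc[:, 0].to_numpy()
        r = np.corrcoef(ours[:, 0], theirs)[0, 1]
        assert abs(r) > 0.9999

    def test_variance_explained_in_unit_interval(self, small_tree, small_cfg):
        truth, _ = synthetic.generate_trait_table(small_tree, small_cfg)
        axis = diet_axis(truth[DIET_COLS])
        assert 0 < axis.variance_explained <= 1

    def test_identical_rows_rejected(self):
        X = np.tile([1 / 7] * 7, (5, 1))
        with pytest.raises(ValueError):
            diet_axis(diet_frame(X))


class TestTransformTraits:
    @staticmethod
    def raw_frame(n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "body_mass": rng.lognormal(4, 1, n),
                "litter_clutch": rng.integers(1, 12, n).astype(float),
                "habitat_breadth": rng.integers(1, 20, n).astype(float),
                "generation_length": rng.lognormal(1, 0.5, n),
                "diet": rng.normal(0, 1, n),
            },
            index=[f"sp{i}" for i in range(n)],
        )

    def test_zero_mean_unit_variance(self):
        z, _ = transform_traits(self.raw_frame())
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_round_trip_inverse(self):
        raw = self.raw_frame()
        z, tf = transform_traits(raw)
        back = tf.inverse(z)
        assert np.allclose(back, raw, rtol=1e-9)

    def test_non_positive_mass_rejected(self):
        raw = self.raw_frame()
        raw.iloc[0, raw.columns.get_loc("body_mass")] = 0.0
        with pytest.raises(ValueError, match="body_mass"):
            transform_traits(raw)

    def test_constant_column_rejected(self):
        raw = self.raw_frame()
        raw["habitat_breadth"] = 4.0
        with pytest.raises(ValueError, match="zero-variance"):
            transform_traits(raw)

    def test_nan_entries_preserved(self):
        raw = self.raw_frame()
        raw.iloc[3, raw.columns.get_loc("diet")] = np.nan
        z, _ = transform_traits(raw)
        assert np.isnan(z.iloc[3]["diet"])


class TestPhyloEigenvectors:
    def test_orthogonality(self, small_tree):
        ev = phylo_eigenvectors(small_tree, k=10)
        G = ev.to_numpy().T @ ev.to_numpy()
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_star_phylogeny_matches_dense_eigendecomposition(self):
        n = 8
        newick = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        ev = phylo_eigenvectors(tree, k=3)
        # oracle: dense double-centering of the known equal-distance matrix
        D = np.full((n, n), 2.0)
        np.fill_diagonal(D, 0.0)
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D**2 @ J
        vals = np.sort(np.linalg.eigvalsh(B))[::-1]
        col_norms = (ev.to_numpy() ** 2).sum(axis=0)
        assert np.allclose(np.sort(col_norms)[::-1], vals[:3], atol=1e-8)

    def test_two_clade_tree_first_vector_separates_clades(self):
        left = "(" + ",".join(f"l{i}:1.0" for i in range(5)) + "):5.0"
        right = "(" + ",".join(f"r{i}:1.0" for i in range(5)) + "):5.0"
        tree = dendropy.Tree.get(data=f"({left},{right});", schema="newick")
        ev = phylo_eigenvectors(tree, k=2)
        signs = np.sign(ev["phylo_ev1"])
        left_signs = {signs[t] for t in ev.index if t.startswith("l")}
        right_signs = {signs[t] for t in ev.index if t.startswith("r")}
        assert len(left_signs) == 1 and len(right_signs) == 1
        assert left_signs != right_signs

    def test_sign_convention_largest_entry_positive(self, small_tree):
        ev = phylo_eigenvectors(small_tree, k=5)
        V = ev.to_numpy()
        for j in range(V.shape[1]):
            assert V[np.argmax(np.abs(V[:, j])), j] > 0

    def test_duplicate_tips_rejected(self):
        tree = synthetic.generate_phylogeny(4, seed=1)
        leaves = tree.leaf_nodes()
        leaves[1].taxon.label = leaves[0].taxon.label
        with pytest.raises(ValueError, match="duplicate"):
            phylo_eigenvectors(tree, k=1)

    def test_k_too_large_rejected(self, small_tree):
        with pytest.raises(ValueError):
            phylo_eigenvectors(small_tree, k=10_000)


from predniche.experiments import imputation_recovery_setup as _impute_setup  # noqa: E402


class TestRfImpute:
    CFG = ImputationConfig(n_sets=2, n_trees=100, seed=0)

    def test_no_missingness_identity(self):
        _, z_truth, _, eig = _impute_setup(n=80, missingness=0.0, seed=3)
        result = rf_impute(z_truth, eig, ImputationConfig(n_sets=1, n_trees=30))
        assert result.sets[0].equals(z_truth)
        assert result.oob_nrmse_mean.notna().all()

    def test_observed_entries_bit_identical(self):
        _, _, z_masked, eig = _impute_setup(n=120, seed=4)
        result = rf_impute(z_masked, eig, self.CFG)
        obs = z_masked.notna()
        for s in result.sets:
            assert s[obs].equals(z_masked[obs])
            assert s.notna().all().all()

    def test_fully_missing_trait_rejected(self):
        _, _, z_masked, eig = _impute_setup(n=60, seed=5)
        z_masked["diet"] = np.nan
        with pytest.raises(ValueError, match="diet"):
            rf_impute(z_masked, eig, self.CFG)

    def test_recovery_under_strong_signal(self):
        """Held-out recovery r >= 0.7 per continuous trait (20% MCAR,
        strong phylogenetic signal lambda=0.95, n=300) across seeds 1-5."""
        cfg = ImputationConfig(n_sets=1, n_trees=100, seed=0)
        for seed in range(1, 6):
            _, z_truth, z_masked, eig = _impute_setup(
                n=300, phylo_signal=0.95, missingness=0.2, seed=seed
            )
            result = rf_impute(z_masked, eig, cfg)
            filled = result.sets[0]
            for col in z_masked.columns:
                held_out = z_masked[col].isna() & z_truth[col].notna()
                if held_out.sum() < 10:
                    continue
                r = np.corrcoef(filled.loc[held_out, col],
                                z_truth.loc[held_out, col])[0, 1]
                assert r >= 0.7, (seed, col, r)

    def test_eigenvectors_improve_recovery(self):
        """Ablation: with phylo_signal=0.9, mean held-out correlation is
        strictly higher with phylogenetic eigenvectors than without."""
        cfg = ImputationConfig(n_sets=1, n_trees=100, seed=0)
        gains = []
        for seed in range(1, 6):
            _, z_truth, z_masked, eig = _impute_setup(
                n=200, phylo_signal=0.9, missingness=0.2, seed=seed
            )
            zero_eig = eig * 0.0
            rs = {}
            for label, vectors in (("with", eig), ("without", zero_eig)):
                filled = rf_impute(z_masked, vectors, cfg).sets[0]
                cors = []
                for col in z_masked.columns:
                    held_out = z_masked[col].isna() & z_truth[col].notna()
                    if held_out.sum() >= 10:
                        cors.append(
                            np.corrcoef(filled.loc[held_out, col],
                                        z_truth.loc[held_out, col])[0, 1]
                        )
                rs[label] = np.mean(cors)
            gains.append(rs["with"] - rs["without"])
        assert np.mean(gains) > 0

    def test_nrmse_monotone_in_missingness(self):
        """Median OOB NRMSE does not decrease as missingness grows."""
        cfg = ImputationConfig(n_sets=1, n_trees=60, seed=0)
        medians = []
        for miss in (0.1, 0.3, 0.5):
            vals = []
            for seed in range(1, 6):
                _, _, z_masked, eig = _impute_setup(
                    n=150, phylo_signal=0.8, missingness=miss, seed=seed
                )
                res = rf_impute(z_masked, eig, cfg)
                vals.append(res.oob_nrmse_mean.mean())
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] + 0.02
        assert medians[1] <= medians[2] + 0.02

    def test_oob_nrmse_plausible_range(self):
        _, _, z_masked, eig = _impute_setup(n=150, seed=6)
        res = rf_impute(z_masked, eig, self.CFG)
        assert ((res.oob_nrmse_mean >= 0) & (res.oob_nrmse_mean <= 1.5)).all()
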