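import numpy as np
import pytest

from tmhc import features, geometry
from tmhc.contacts import enumerate_candidates
from tmhc.features import (
    CF_DIM,
    SDF_DIM,
    apply_scaler,
    build_dataset,
    cf_vector,
    compute_helix_axes,
    fit_scaler,
    neighbor_window,
    sdf_vector,
)
from .conftest import random_rotation


class TestNeighborWindow:
    def test_order_and_exclusion(self):
        window = neighbor_window(10, 20)
        assert len(window) == 8
        assert window[0] == (9, 19)
        assert window[-1] == (11, 21)
        assert (10, 20) not in window
        assert window == [
            (9, 19), (9, 20), (9, 21), (10, 19), (10, 21), (11, 19), (11, 20), (11, 21)
        ]

    def test_disjoint_middle_rows(self):
        w1 = set(neighbor_window(5, 20))
        w2 = set(neighbor_window(7, 20))
        assert not {p for p in w1 if p[0] == 5} & {p for p in w2 if p[0] == 7}


class TestSdfVector:
    def test_interior_pair_blocks_match_pair_geometry(self, two_helix_bundle):
        chain, ann, _ = two_helix_bundle
        axes = compute_helix_axes(chain, ann)
        pairs = enumerate_candidates(chain, ann)
        pair = next(
            p
            for p in pairs
            if ann.segments[0][0] < p.i < ann.segments[0][1]
            and ann.segments[1][0] < p.j < ann.segments[1][1]
        )
        vec, mask = sdf_vector(chain, ann, pair, axes)
        assert vec.shape == (SDF_DIM,)
        assert mask.all()
        for k, (p, q) in enumerate(neighbor_window(pair.i, pair.j)):
            h1 = ann.helix_of(p) or pair.helix_i
            h2 = ann.helix_of(q) or pair.helix_j
            g = geometry.pair_geometry(
                chain.residue(p), chain.residue(q), axes[h1], axes[h2]
            )
            expected = np.round(g.as_array() / 1e-6) * 1e-6
            np.testing.assert_array_equal(vec[5 * k : 5 * k + 5], expected)

    def test_terminus_blocks_zeroed(self, two_helix_bundle):
        chain, ann, _ = two_helix_bundle
        axes = compute_helix_axes(chain, ann)
        pairs = enumerate_candidates(chain, ann)
        first = chain.positions()[0]
        pair = next(p for p in pairs if p.i == first)  # i-1 outside the chain
        vec, mask = sdf_vector(chain, ann, pair, axes)
        assert not mask[0] and not mask[1] and not mask[2]
        np.testing.assert_array_equal(vec[:15], np.zeros(15))

    def test_bit_identical_under_rigid_transform(self, two_helix_bundle, rng):
        chain, ann, _ = two_helix_bundle
        pairs = enumerate_candidates(chain, ann)
        axes = compute_helix_axes(chain, ann)
        moved = chain.transformed(random_rotation(rng), rng.uniform(-30, 30, 3))
        axes_m = compute_helix_axes(moved, ann)
        for pair in pairs[::7]:
            v1, _ = sdf_vector(chain, ann, pair, axes)
            v2, _ = sdf_vector(moved, ann, pair, axes_m)
            np.testing.assert_array_equal(v1, v2)


class TestCfVector:
    def test_dimensions_and_block_layout(self, two_helix_bundle):
        chain, ann, _ = two_helix_bundle
        pair = enumerate_candidates(chain, ann)[10]
        vec, mask = cf_vector(chain, pair)
        assert vec.shape == (CF_DIM,)
        # a fully valid block holds the raw N coordinates of the row residue
        k = int(np.flatnonzero(mask)[0])
        p, q = features.neighbor_window(pair.i, pair.j)[k]
        np.testing.assert_array_equal(
            vec[24 * k : 24 * k + 3], chain.residue(p).atoms["N"]
        )

    def test_translation_shifts_x_coordinates(self, two_helix_bundle):
        chain, ann, _ = two_helix_bundle
        pair = enumerate_candidates(chain, ann)[10]
        vec, mask = cf_vector(chain, pair)
        shifted = chain.transformed(np.eye(3), np.array([10.0, 0.0, 0.0]))
        vec2, _ = cf_vector(shifted, pair)
        for k in np.flatnonzero(mask):
            block = slice(24 * k, 24 * (k + 1))
            diff = (vec2[block] - vec[block]).reshape(8, 3)
            np.testing.assert_allclose(diff, np.tile([10.0, 0.0, 0.0], (8, 1)))

    def test_glycine_cb_falls_back_to_ca(self, two_helix_bundle):
        chain, ann, _ = two_helix_bundle
        pair = enumerate_candidates(chain, ann)[10]
        stripped = chain.transformed(np.eye(3), np.zeros(3))
        for r in stripped.residues:
            r.atoms.pop("CB", None)
        vec, mask = cf_vector(stripped, pair)
        k = int(np.flatnonzero(mask)[0])
        p, _ = features.neighbor_window(pair.i, pair.j)[k]
        block = vec[24 * k : 24 * k + 12]
        np.testing.assert_array_equal(block[9:12], stripped.residue(p).atoms["CA"])


class TestScaler:
    def test_worked_examples(self):
        X = np.array([[2.0], [4.0]])
        params = fit_scaler(X)
        assert apply_scaler(np.array([[3.0]]), params)[0, 0] == pytest.approx(0.0)
        assert apply_scaler(np.array([[2.0]]), params)[0, 0] == -1.0
        assert apply_scaler(np.array([[4.0]]), params)[0, 0] == 1.0

    def test_training_matrix_maps_into_unit_box(self, rng):
        X = rng.normal(size=(50, 7)) * rng.uniform(0.1, 10, size=7)
        scaled = apply_scaler(X, fit_scaler(X))
        np.testing.assert_allclose(scaled.min(axis=0), -1.0, atol=1e-12)
        np.testing.assert_allclose(scaled.max(axis=0), 1.0, atol=1e-12)

    def test_constant_column_maps_to_minus_one(self):
        X = np.full((5, 2), 3.0)
        X[:, 1] = np.arange(5)
        scaled = apply_scaler(X, fit_scaler(X))
        np.testing.assert_array_equal(scaled[:, 0], -1.0)

    def test_test_values_may_leave_range(self):
        params = fit_scaler(np.array([[0.0], [1.0]]))
        assert apply_scaler(np.array([[2.0]]), params)[0, 0] == pytest.approx(3.0)

    def test_width_mismatch_rejected(self):
        params = fit_scaler(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="columns"):
            apply_scaler(np.zeros((3, 5)), params)


class TestBuildDataset:
    @pytest.fixture(scope="class")
    def toy(self):
        from tmhc.synthetic import BundleSpec, make_bundle

        # 6-residue helices are below the generator minimum; use a small bundle
        spec = BundleSpec(n_helices=2, helix_length=12, seed=5)
        chain, ann, _ = make_bundle(spec)
        return chain, ann

    def test_matrix_shapes(self, toy):
        chain, ann = toy
        n = len(enumerate_candidates(chain, ann))
        sdf = build_dataset({"A": chain}, {"A": ann}, "SDF")
        cf = build_dataset({"A": chain}, {"A": ann}, "CF")
        assert sdf.X.shape == (n, SDF_DIM)
        assert cf.X.shape == (n, CF_DIM)
        assert len(sdf.labels) == n

    def test_canonical_row_order(self, toy):
        chain, ann = toy
        fs = build_dataset({"A": chain}, {"A": ann}, "SDF")
        keys = [(c, p.i, p.j) for c, p in zip(fs.chain_ids, fs.pairs)]
        assert keys == sorted(keys)

    def test_cf_matrix_changes_under_rigid_transform(self, toy, rng):
        chain, ann = toy
        moved = chain.transformed(random_rotation(rng), rng.uniform(-30, 30, 3))
        cf1 = build_dataset({"A": chain}, {"A": ann}, "CF")
        cf2 = build_dataset({"A": moved}, {"A": ann}, "CF")
        assert not np.array_equal(cf1.X, cf2.X)


def test_sdf_statistics_shift_less_than_cf_across_structure_sources(study_dataset):
    """Pooled mean/SD of scaled SDF matrices barely move between a clean
    structure and its predicted-structure twin (own frame + 0.5 A noise),
    while CF statistics move substantially - the distribution-stability
    property that makes SDFs transferable across structure sources."""
    from tmhc.evaluation import feature_statistics
    from tmhc.synthetic import predicted_twin

    chains, anns, _ = study_dataset
    twins = {
        cid: predicted_twin(ch, 0.5, seed=k)
        for k, (cid, ch) in enumerate(sorted(chains.items()))
    }
    shifts = {}
    for kind in ("SDF", "CF"):
        fs_clean = build_dataset(chains, anns, kind)
        fs_twin = build_dataset(twins, anns, kind, label_structures=chains)
        scaler = fit_scaler(fs_clean.X)
        m0, s0 = feature_statistics(apply_scaler(fs_clean.X, scaler))
        m1, s1 = feature_statistics(apply_scaler(fs_twin.X, scaler))
        shifts[kind] = (abs(m1 - m0), abs(s1 - s0))
    assert shifts["SDF"][0] < shifts["CF"][0]  # mean shift
    assert shifts["SDF"][1] < shifts["CF"][1]  # SD shift
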