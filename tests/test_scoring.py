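"""Signature scores, ROI means and standardization against loop oracles."""

import numpy as np
import pandas as pd
import pytest

from twinplacebo.scoring import (
    GridMismatchError,
    SignatureMap,
    VolumeMap,
    local_pattern_response,
    regrid,
    roi_mean,
    signature_score,
    zscore_within,
)

from oracles import loop_roi_mean, loop_signature_score


@pytest.fixture()
def fixture_pair(rng):
    """A 6x6x6 map/signature pair with partial, overlapping masks."""
    shape = (6, 6, 6)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    values = rng.standard_normal(shape)
    weights = rng.standard_normal(shape)
    map_mask = rng.random(shape) > 0.2
    atlas = np.zeros(shape, dtype=int)
    atlas[:3, :3, :3] = 1
    atlas[3:, 3:, 3:] = 2
    weights[atlas == 1] = np.abs(weights[atlas == 1])
    weights[atlas == 2] = -np.abs(weights[atlas == 2])
    sig_mask = atlas > 0
    vmap = VolumeMap(values=values, affine=affine, mask=map_mask)
    sig = SignatureMap(
        values=weights, affine=affine, mask=sig_mask,
        subregions=atlas, subregion_signs={1: 1, 2: -1},
    )
    return vmap, sig


class TestSignatureScore:
    def test_matches_triple_loop(self, fixture_pair):
        vmap, sig = fixture_pair
        joint = vmap.mask & sig.mask
        expected = loop_signature_score(vmap.values, sig.values, joint)
        assert signature_score(vmap, sig) == pytest.approx(expected, rel=1e-12)

    def test_zero_map_scores_zero(self, fixture_pair):
        _, sig = fixture_pair
        zero = VolumeMap(
            values=np.zeros_like(sig.values), affine=sig.affine, mask=np.ones(sig.values.shape, bool)
        )
        assert signature_score(zero, sig) == 0.0

    def test_linearity(self, fixture_pair, rng):
        vmap, sig = fixture_pair
        other = VolumeMap(
            values=rng.standard_normal(vmap.values.shape),
            affine=vmap.affine, mask=vmap.mask,
        )
        combo = VolumeMap(
            values=2.0 * vmap.values - 0.5 * other.values,
            affine=vmap.affine, mask=vmap.mask,
        )
        assert signature_score(combo, sig) == pytest.approx(
            2.0 * signature_score(vmap, sig) - 0.5 * signature_score(other, sig),
            rel=1e-10,
        )

    def test_values_outside_joint_mask_are_ignored(self, fixture_pair):
        vmap, sig = fixture_pair
        tampered = vmap.values.copy()
        tampered[~sig.mask] = 1e6
        vmap2 = VolumeMap(values=tampered, affine=vmap.affine, mask=vmap.mask)
        assert signature_score(vmap2, sig) == pytest.approx(
            signature_score(vmap, sig), rel=1e-12
        )

    def test_grid_mismatch_raises(self, fixture_pair):
        vmap, sig = fixture_pair
        shifted = VolumeMap(
            values=vmap.values, affine=vmap.affine + np.diag([0.1, 0, 0, 0]), mask=vmap.mask
        )
        with pytest.raises(GridMismatchError):
            signature_score(shifted, sig)


class TestRoiMean:
    def test_constant_map(self, fixture_pair):
        vmap, _ = fixture_pair
        const = VolumeMap(
            values=np.full(vmap.values.shape, 3.25), affine=vmap.affine,
            mask=np.ones(vmap.values.shape, bool),
        )
        roi = np.zeros(vmap.values.shape, bool)
        roi[1:4, 2, 2] = True
        assert roi_mean(const, roi) == pytest.approx(3.25)

    def test_matches_loop_oracle(self, fixture_pair):
        vmap, _ = fixture_pair
        roi = np.zeros(vmap.values.shape, bool)
        roi[2:5, 1:4, 0:3] = True
        joint = roi & vmap.mask
        assert roi_mean(vmap, roi) == pytest.approx(
            loop_roi_mean(vmap.values, joint), rel=1e-12
        )

    def test_uniform_weight_signature_equals_roi_mean(self, rng):
        shape = (6, 6, 6)
        affine = np.eye(4)
        roi = np.zeros(shape, bool)
        roi[1:4, 1:4, 1:4] = True
        n = roi.sum()
        weights = np.where(roi, 1.0 / n, 0.0)
        sig = SignatureMap(
            values=weights, affine=affine, mask=roi,
            subregions=roi.astype(int), subregion_signs={1: 1},
        )
        vmap = VolumeMap(
            values=rng.standard_normal(shape), affine=affine, mask=np.ones(shape, bool)
        )
        assert signature_score(vmap, sig) == pytest.approx(roi_mean(vmap, roi), rel=1e-10)

    def test_empty_intersection_raises(self, fixture_pair):
        vmap, _ = fixture_pair
        with pytest.raises(ValueError, match="intersect"):
            roi_mean(vmap, np.zeros(vmap.values.shape, bool))


class TestLocalPatternResponse:
    def test_partition_additivity(self, fixture_pair):
        vmap, sig = fixture_pair
        total = sum(
            local_pattern_response(vmap, sig, label) for label in sig.labels()
        )
        assert total == pytest.approx(signature_score(vmap, sig), rel=1e-10)

    def test_negative_weights_negative_activity_gives_positive_response(self, fixture_pair):
        _, sig = fixture_pair
        deact = VolumeMap(
            values=np.full(sig.values.shape, -1.0), affine=sig.affine,
            mask=np.ones(sig.values.shape, bool),
        )
        assert local_pattern_response(deact, sig, 2) > 0

    def test_matches_loop_oracle(self, fixture_pair):
        vmap, sig = fixture_pair
        sel = (sig.subregions == 1) & vmap.mask
        assert local_pattern_response(vmap, sig, 1) == pytest.approx(
            loop_signature_score(vmap.values, sig.values, sel), rel=1e-12
        )

    def test_unknown_label_raises(self, fixture_pair):
        vmap, sig = fixture_pair
        with pytest.raises(KeyError):
            local_pattern_response(vmap, sig, 99)


class TestZscoreWithin:
    def test_unit_moments_per_group(self, rng):
        df = pd.DataFrame(
            {
                "modality": np.repeat(["thermal", "mechanical"], 50),
                "score": rng.standard_normal(100) * 3 + 1,
            }
        )
        out = zscore_within(df, ["modality"])
        for _, grp in out.groupby("modality"):
            assert abs(grp["score"].mean()) < 1e-12
            assert abs(grp["score"].std(ddof=1) - 1) < 1e-12

    def test_three_point_example(self):
        df = pd.DataFrame({"g": ["a"] * 3, "score": [1.0, 2.0, 3.0]})
        out = zscore_within(df, ["g"])
        assert np.allclose(out["score"], [-1.0, 0.0, 1.0])

    def test_groups_transformed_independently(self, rng):
        df = pd.DataFrame(
            {"g": ["a"] * 10 + ["b"] * 10, "score": rng.standard_normal(20)}
        )
        out_a = zscore_within(df[df.g == "a"].copy(), ["g"])
        combined = zscore_within(df, ["g"])
        assert np.allclose(
            combined[combined.g == "a"]["score"].to_numpy(), out_a["score"].to_numpy()
        )

    def test_constant_group_raises_with_name(self):
        df = pd.DataFrame({"g": ["bad"] * 4, "score": [2.0] * 4})
        with pytest.raises(ValueError, match="bad"):
            zscore_within(df, ["g"])


class TestScoreLinearityProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        alpha=st.floats(-5, 5, allow_nan=False),
        beta=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_score_is_linear_in_the_map(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        shape = (6, 6, 6)
        affine = np.eye(4)
        mask = np.ones(shape, bool)
        sig = SignatureMap(
            values=np.abs(rng.standard_normal(shape)), affine=affine, mask=mask,
            subregions=mask.astype(int), subregion_signs={1: 1},
        )
        a = rng.standard_normal(shape)
        b = rng.standard_normal(shape)
        combo = VolumeMap(values=alpha * a + beta * b, affine=affine, mask=mask)
        va = VolumeMap(values=a, affine=affine, mask=mask)
        vb = VolumeMap(values=b, affine=affine, mask=mask)
        lhs = signature_score(combo, sig)
        rhs = alpha * signature_score(va, sig) + beta * signature_score(vb, sig)
        assert lhs == pytest.approx(rhs, abs=1e-8 * (1 + abs(rhs)))


def test_regrid_is_explicit_and_warns(fixture_pair):
    vmap, _ = fixture_pair
    target = VolumeMap(
        values=np.zeros((12, 12, 12)), affine=np.diag([1.5, 1.5, 1.5, 1.0]),
        mask=np.ones((12, 12, 12), bool),
    )
    with pytest.warns(UserWarning, match="regrid"):
        out = regrid(vmap, target, order=0)
    assert out.values.shape == (12, 12, 12)


def test_nifti_roundtrip(tmp_path, signature):
    from twinplacebo.scoring import load_signature
    from twinplacebo.synth import write_signature

    write_signature(signature, tmp_path)
    back = load_signature(tmp_path)
    assert np.allclose(back.weights, signature.weights)
    assert np.array_equal(back.subregions, signature.subregions)
    assert back.subregion_signs == signature.subregion_signs
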