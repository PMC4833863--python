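"""Unit and property tests for the invasion-stack quantification stages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellquant import invasion as inv
from cellquant import synthetic as syn


def brute_force_otsu(values, n_bins=256):
    """Exhaustive between-class-variance search over all interior bin edges."""
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_edge = -1.0, None
    for k in range(n_bins - 1):
        w0 = counts[:k + 1].sum()
        w1 = counts[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k + 1] * centers[:k + 1]).sum() / w0
        m1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_edge = var, edges[k + 1]
    return best_edge


def _as_stack(values):
    arr = np.asarray(values, dtype=float).ravel()
    return inv.ImageStack(voxels=np.tile(arr, 2).reshape(2, 1, -1))


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self):
        vals = np.concatenate([np.full(900, 10.0), np.full(100, 200.0)])
        thr = inv.otsu_threshold(_as_stack(vals))
        assert 10.0 < thr <= 200.0

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inv.otsu_threshold(_as_stack(np.full(64, 7.0)))

    def test_matches_exhaustive_oracle_on_random_histograms(self, rng):
        for _ in range(100):
            vals = rng.integers(0, 256, size=int(rng.integers(20, 500))).astype(float)
            if vals.min() == vals.max():
                continue
            assert inv.otsu_threshold(_as_stack(vals)) == pytest.approx(
                brute_force_otsu(vals))


class TestSubtractAndProfile:
    def test_subtract_forced_arithmetic(self):
        stack = _as_stack([0.0, 5.0, 12.0])
        out = inv.subtract_threshold(stack, 5.0)
        assert np.array_equal(np.unique(out.voxels), [0.0, 7.0])

    def test_subtract_zero_is_identity_and_saturation_zeroes(self):
        stack = _as_stack([1.0, 2.0, 3.0])
        assert np.array_equal(inv.subtract_threshold(stack, 0.0).voxels, stack.voxels)
        assert not inv.subtract_threshold(stack, 99.0).voxels.any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            inv.subtract_threshold(_as_stack([1.0, 2.0]), -1.0)

    def test_profile_delta_and_conservation(self, rng):
        vox = np.zeros((6, 4, 4))
        vox[3, 2, 1] = 7.0
        prof = inv.z_profile(inv.ImageStack(voxels=vox))
        assert prof.intensity[3] == 7.0 and prof.intensity.sum() == 7.0

        vox = rng.random((8, 5, 5))
        prof = inv.z_profile(inv.ImageStack(voxels=vox))
        assert prof.intensity.sum() == pytest.approx(vox.sum(), rel=1e-12)


class TestAlignment:
    def test_single_profile_identity(self):
        p = inv.ZProfile(intensity=[0.0, 5.0, 1.0])
        out = inv.align_profiles([p])
        assert out.pad_offsets.tolist() == [0]
        assert np.array_equal(out.profiles[0], p.intensity)

    def test_forced_padding_example(self):
        a = inv.ZProfile(intensity=[0.0, 5.0, 1.0])
        b = inv.ZProfile(intensity=[5.0, 1.0, 0.0])
        out = inv.align_profiles([a, b])
        assert out.common_max_index == 1
        assert np.array_equal(out.profiles[1], [0.0, 5.0, 1.0, 0.0])
        assert all(int(np.argmax(row)) == 1 for row in out.profiles)

    def test_shift_recovery_over_random_shifts(self, rng):
        template = rng.random(30)
        template[8] = 2.0  # unique maximum
        profiles = []
        for _ in range(20):
            s = int(rng.integers(0, 10))
            profiles.append(inv.ZProfile(intensity=np.concatenate(
                [np.zeros(s), template])))
        out = inv.align_profiles(profiles)
        base = out.profiles[:, out.common_max_index - 8:out.common_max_index - 8 + 30]
        assert np.allclose(base, template)

    def test_idempotence(self, rng):
        profiles = [inv.ZProfile(intensity=np.concatenate([np.zeros(k), [3.0], rng.random(5)]))
                    for k in range(4)]
        once = inv.align_profiles(profiles)
        twice = inv.align_profiles([inv.ZProfile(intensity=row) for row in once.profiles])
        assert np.array_equal(once.profiles, twice.profiles)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            inv.align_profiles([])


class TestHorizon:
    def _aligned(self, mean_profile):
        return inv.AlignedProfileSet(
            profiles=np.asarray([mean_profile], dtype=float),
            common_max_index=int(np.argmax(mean_profile)),
            pad_offsets=np.zeros(1, dtype=int))

    def test_fixed_offset_definition(self):
        aligned = self._aligned([0, 1, 2, 3, 4, 10, 4, 3, 2, 1, 0])
        assert inv.select_horizon(aligned, "fixed:3") == 8

    def test_fraction_of_max_rule(self):
        aligned = self._aligned([0.0, 1.0, 10.0, 4.0, 0.9, 0.2])
        assert inv.select_horizon(aligned, "frac:0.1") == 4

    def test_fixed_offset_beyond_length_rejected(self):
        aligned = self._aligned([0.0, 10.0, 1.0])
        with pytest.raises(ValueError):
            inv.select_horizon(aligned, "fixed:5")

    def test_rule_recorded_in_metadata(self):
        aligned = self._aligned([0, 10, 4, 1, 0, 0, 0])
        inv.select_horizon(aligned, "fixed:2")
        assert aligned.horizon_meta == {"rule": "fixed", "parameter": 2.0,
                                        "horizon": 3, "common_max_index": 1}


class TestInvasionValue:
    @pytest.mark.parametrize("profile,horizon,expected", [
        ([0.0, 0.0, 100.0], 1, 1.0),
        ([10.0, 20.0, 30.0], 2, 0.0),
        ([10.0, 10.0, 20.0, 40.0, 20.0], 2, 0.6),
    ])
    def test_forced_arithmetic(self, profile, horizon, expected):
        res = inv.invasion_value(np.asarray(profile), horizon)
        assert res.invasion_value == pytest.approx(expected)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="no cell signal"):
            inv.invasion_value(np.zeros(5), 2)

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2, max_size=30),
           st.integers(min_value=0, max_value=29))
    @settings(max_examples=100, deadline=None)
    def test_value_always_in_unit_interval(self, profile, horizon):
        arr = np.asarray(profile)
        if arr.sum() <= 0 or horizon >= len(arr):
            return
        v = inv.invasion_value(arr, horizon).invasion_value
        assert 0.0 <= v <= 1.0


class TestAnova:
    def test_hand_computed_fixture(self):
        res = inv.one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.f_stat == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_matches_scipy(self, rng):
        from scipy.stats import f_oneway
        groups = {k: rng.normal(size=12) for k in "abc"}
        res = inv.one_way_anova(groups)
        ref = f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_identical_groups_give_f_zero_p_one(self):
        res = inv.one_way_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_degenerate_zero_within_variance(self):
        res = inv.one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.p_value == 0.0 and res.degenerate

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            inv.one_way_anova({"a": [1.0], "b": [1.0, 2.0]})


class TestPipeline:
    def test_group_separation_and_ordering(self):
        stacks, labels = [], []
        for i, (f, g) in enumerate([(0.05, "ctrl")] * 3 + [(0.5, "egf")] * 3):
            spec = syn.InvasionPhantomSpec(nx=96, ny=96, n_cells=40,
                                           invaded_fraction=f, seed=20 + i)
            stack, _ = syn.gen_invasion_stack(spec)
            stack.source_id = f"img{i}"
            stacks.append(stack)
            labels.append(g)
        table, anova, aligned = inv.quantify_stacks(stacks, labels)
        means = table.groupby("group")["invasion_value"].mean()
        assert means["ctrl"] < means["egf"]
        assert anova.p_value < 0.01

    def test_identical_stacks_in_both_groups_f_zero(self, noiseless_phantom):
        _, stack, _ = noiseless_phantom
        table, anova, _ = inv.quantify_stacks([stack] * 4, ["a", "a", "b", "b"])
        assert anova.f_stat == 0.0

    def test_stage_error_names_offending_image(self):
        good, _ = syn.gen_invasion_stack(syn.InvasionPhantomSpec(nx=64, ny=64,
                                                                 n_cells=20, seed=1))
        bad = inv.ImageStack(voxels=np.full((5, 4, 4), 3.0), source_id="flat.tif")
        with pytest.raises(ValueError, match="flat.tif"):
            inv.quantify_stacks([good, bad], ["a", "a"])


class TestStackIO:
    def test_roundtrip(self, tmp_path, noiseless_phantom):
        _, stack, _ = noiseless_phantom
        path = tmp_path / "stack.tif"
        inv.write_stack(stack, path)
        back = inv.read_stack(path, z_step=stack.z_step)
        assert np.array_equal(back.voxels, stack.voxels)

    def test_known_pages_roundtrip(self, tmp_path):
        vox = np.arange(48, dtype=np.float32).reshape(3, 4, 4)
        path = tmp_path / "t.tif"
        inv.write_stack(inv.ImageStack(voxels=vox), path)
        assert np.array_equal(inv.read_stack(path).voxels, vox)

    def test_single_page_rejected(self, tmp_path):
        import tifffile
        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.ones((4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="not a stack"):
            inv.read_stack(path)

    def test_unreadable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.tif"
        path.write_bytes(b"this is not a TIFF")
        with pytest.raises(ValueError):
            inv.read_stack(path)
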