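import numpy as np
import pytest

from retinakit import synth
from retinakit.morphology import (
    IplFrame,
    Morphology,
    SwcValidationError,
    branch_points,
    classify_subtype,
    read_swc,
    stratification_distribution,
    total_neurite_length,
    write_swc,
)
from retinakit.profiles import StratificationProfile, stratum_of


def brute_force_length(m: Morphology, excluded={1, 2}) -> float:
    id_to_row = {int(i): k for k, i in enumerate(m.ids)}
    total = 0.0
    for k in range(m.n):
        if m.parents[k] == -1 or m.types[k] in excluded:
            continue
        p = id_to_row[int(m.parents[k])]
        total += float(np.sqrt(((m.xyz[k] - m.xyz[p]) ** 2).sum()))
    return total


def brute_force_branch_points(m: Morphology) -> int:
    children = {}
    for k in range(m.n):
        if m.parents[k] != -1:
            children[int(m.parents[k])] = children.get(int(m.parents[k]), 0) + 1
    return sum(1 for k in range(m.n)
               if m.types[k] != 1 and children.get(int(m.ids[k]), 0) >= 2)


def make_path(n=5, step=10.0):
    """Unbranched dendrite path along x."""
    ids = np.arange(1, n + 1)
    return Morphology(
        ids=ids,
        types=np.r_[1, np.full(n - 1, 3)],
        xyz=np.column_stack([np.arange(n) * step, np.zeros(n), np.zeros(n)]),
        radii=np.ones(n),
        parents=np.r_[-1, ids[:-1]],
    )


class TestSwcIO:
    def test_minimal_file(self, tmp_path):
        f = tmp_path / "cell.swc"
        f.write_text("# comment\n1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n3 3 20 0 0 1 2\n")
        m = read_swc(f)
        assert m.n == 3
        assert total_neurite_length(m) == pytest.approx(20.0)

    def test_roundtrip_identity(self, tmp_path):
        m = synth.gen_morphology(strat_depths=[30, 70], seed=1)
        f = tmp_path / "cell.swc"
        write_swc(m, f)
        m2 = read_swc(f)
        np.testing.assert_array_equal(m.ids, m2.ids)
        np.testing.assert_array_equal(m.types, m2.types)
        np.testing.assert_array_equal(m.parents, m2.parents)
        np.testing.assert_allclose(m.xyz, m2.xyz, atol=1e-6)

    def test_cycle_rejected(self, tmp_path):
        f = tmp_path / "bad.swc"
        f.write_text("1 1 0 0 0 5 3\n2 3 1 0 0 1 1\n3 3 2 0 0 1 2\n")
        with pytest.raises(SwcValidationError):
            read_swc(f)

    def test_missing_parent_rejected(self, tmp_path):
        f = tmp_path / "bad.swc"
        f.write_text("1 1 0 0 0 5 -1\n2 3 1 0 0 1 99\n")
        with pytest.raises(SwcValidationError, match="parent 99"):
            read_swc(f)

    def test_duplicate_ids_rejected(self, tmp_path):
        f = tmp_path / "bad.swc"
        f.write_text("1 1 0 0 0 5 -1\n1 3 1 0 0 1 1\n")
        with pytest.raises(SwcValidationError, match="duplicate"):
            read_swc(f)

    def test_wrong_column_count_rejected(self, tmp_path):
        f = tmp_path / "bad.swc"
        f.write_text("1 1 0 0 0 5\n")
        with pytest.raises(SwcValidationError, match="7 columns"):
            read_swc(f)


class TestTotalNeuriteLength:
    def test_single_segment(self):
        ids = np.array([1, 2])
        m = Morphology(ids=ids, types=np.array([1, 3]),
                       xyz=np.array([[0.0, 0, 0], [30.0, 0, 0]]),
                       radii=np.ones(2), parents=np.array([-1, 1]))
        assert total_neurite_length(m) == pytest.approx(30.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        m = synth.gen_morphology(strat_depths=[20, 60], branch_order=4, seed=seed)
        assert total_neurite_length(m) == pytest.approx(brute_force_length(m),
                                                        rel=1e-12)

    def test_rotation_invariance(self):
        m = synth.gen_morphology(strat_depths=[40], seed=3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        rotated = Morphology(ids=m.ids, types=m.types, xyz=m.xyz @ R.T,
                             radii=m.radii, parents=m.parents)
        assert total_neurite_length(rotated) == pytest.approx(
            total_neurite_length(m), rel=1e-9)

    def test_id_relabeling_invariance(self):
        m = synth.gen_morphology(strat_depths=[40], seed=4)
        relabeled = Morphology(
            ids=m.ids * 10, types=m.types, xyz=m.xyz, radii=m.radii,
            parents=np.where(m.parents == -1, -1, m.parents * 10))
        assert total_neurite_length(relabeled) == total_neurite_length(m)
        assert branch_points(relabeled) == branch_points(m)


class TestBranchPoints:
    def test_unbranched_path(self):
        assert branch_points(make_path(6)) == 0

    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_perfect_binary_tree(self, depth):
        # 2^depth - 1 internal nodes each carry two children
        nodes = [(1, 1, (0.0, 0.0, 0.0), -1)]
        frontier = [1]
        next_id = 2
        for level in range(1, depth + 1):
            new = []
            for parent in frontier:
                for j in range(2):
                    nodes.append((next_id, 3,
                                  (float(next_id), float(level), float(j)), parent))
                    new.append(next_id)
                    next_id += 1
            frontier = new
        ids = np.array([n[0] for n in nodes])
        m = Morphology(
            ids=ids,
            types=np.array([n[1] for n in nodes]),
            xyz=np.array([n[2] for n in nodes]),
            radii=np.ones(len(nodes)),
            parents=np.array([n[3] for n in nodes]),
        )
        # soma is excluded; internal non-soma nodes: 2^depth - 2
        assert branch_points(m) == 2**depth - 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        m = synth.gen_morphology(strat_depths=[50], branch_order=5, seed=seed)
        assert branch_points(m) == brute_force_branch_points(m)


class TestStratificationDistribution:
    FRAME = IplFrame(gcl_border_z=0.0, inl_border_z=50.0)

    def test_planar_arbor_single_bin(self):
        # dendrites all at z=20 μm -> 40% depth
        ids = np.arange(1, 5)
        m = Morphology(
            ids=ids, types=np.array([1, 3, 3, 3]),
            xyz=np.array([[0, 0, 20.0], [10, 0, 20.0], [20, 0, 20.0], [30, 0, 20.0]]),
            radii=np.ones(4), parents=np.array([-1, 1, 2, 3]))
        prof = stratification_distribution(m, self.FRAME, bin=2.0)
        assert prof.raw.sum() == pytest.approx(30.0)
        assert prof.peak_depth == pytest.approx(41.0)  # center of the [40,42) bin
        assert (prof.raw > 0).sum() == 1

    def test_two_slab_peaks(self):
        m = synth.gen_morphology(strat_depths=[30, 70], seed=5)
        frame = synth.frame_from_truth(m.ground_truth)
        prof = stratification_distribution(m, frame, bin=2.0)
        call = classify_subtype(prof)
        assert len(call.peak_depths) == 2
        assert abs(call.peak_depths[0] - 30.0) <= 5.0
        assert abs(call.peak_depths[1] - 70.0) <= 5.0

    def test_mass_conservation(self):
        m = synth.gen_morphology(strat_depths=[40], seed=6, soma_depth=0.0)
        frame = synth.frame_from_truth(m.ground_truth)
        prof = stratification_distribution(m, frame, bin=2.0)
        assert prof.raw.sum() == pytest.approx(total_neurite_length(m), rel=1e-6)

    def test_equal_frame_borders_rejected(self):
        with pytest.raises(ValueError):
            IplFrame(gcl_border_z=10.0, inl_border_z=10.0)

    def test_far_outside_depth_rejected(self):
        m = make_path()
        frame = IplFrame(gcl_border_z=100.0, inl_border_z=150.0)  # depths ~ -200%
        with pytest.raises(ValueError, match="tolerance"):
            stratification_distribution(m, frame)


class TestClassifySubtype:
    def _profile(self, depths, weights):
        bins = np.arange(1.0, 100.0, 2.0)
        sig = np.zeros_like(bins)
        for d, w in zip(depths, weights):
            sig += w * np.exp(-0.5 * ((bins - d) / 4.0) ** 2)
        return StratificationProfile(depth_bins=bins, signal=sig / sig.max(),
                                     raw=sig)

    def test_bistratified_s2_s4(self):
        call = classify_subtype(self._profile([30.0, 70.0], [1.0, 0.9]))
        assert call.call == "bistratified_S2S4"

    def test_mono_off_s1(self):
        call = classify_subtype(self._profile([90.0], [1.0]))
        assert call.call == "mono_OFF_S1"

    def test_mono_on_s4_and_s5(self):
        assert classify_subtype(self._profile([30.0], [1.0])).call == "mono_ON_S4"
        assert classify_subtype(self._profile([10.0], [1.0])).call == "mono_ON_S5"

    def test_flat_profile_unclassified(self):
        bins = np.arange(1.0, 100.0, 2.0)
        prof = StratificationProfile(depth_bins=bins, signal=np.ones_like(bins),
                                     raw=np.ones_like(bins))
        assert classify_subtype(prof).call == "unclassified"

    def test_minor_peak_ignored(self):
        # second peak carries <15% of mass -> monostratified call
        call = classify_subtype(self._profile([30.0, 70.0], [1.0, 0.1]))
        assert call.call == "mono_ON_S4"

    def test_stratum_mapping(self):
        assert stratum_of(10.0) == "S5"
        assert stratum_of(30.0) == "S4"
        assert stratum_of(50.0) == "S3"
        assert stratum_of(70.0) == "S2"
        assert stratum_of(90.0) == "S1"
        assert stratum_of(100.0) == "S1"
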