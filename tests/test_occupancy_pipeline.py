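import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shellkit import occupancy_pipeline as op
from shellkit import structure_io as sio
from shellkit import synthetic_shells as ss


@pytest.fixture(scope="module")
def small_fixture(lattice, default_spec):
    plan = frozenset(lattice.group_members("pentamer", 2)) | frozenset(
        lattice.group_members("dimer", 9)
    )
    spec = ss.with_removal_plan(default_spec, plan)
    full = ss.make_reference_shell(lattice, spec)
    model = ss.make_partial_model(full, plan)
    clean = ss.simulate_density(model, spec.resolution, spec.voxel_size)
    noisy = ss.add_map_noise(clean, spec.snr, seed=spec.seed)
    return full, model, clean, noisy, plan, spec


class TestChainMapCC:
    def test_self_correlation_noise_free(self, small_fixture):
        full, model, clean, _, plan, spec = small_fixture
        cid = model.chain_ids[0]
        cc = op.chain_map_cc(clean, model, cid, spec.resolution)
        assert cc >= 0.99

    def test_deleted_chain_correlates_below_half(self, small_fixture):
        full, model, clean, noisy, plan, spec = small_fixture
        deleted = [c for c, s in full.assignment.items() if s in plan]
        for cid in deleted[:3]:
            cc = op.chain_map_cc(noisy, full, cid, spec.resolution)
            assert cc < 0.5

    def test_scale_and_offset_invariance(self, small_fixture):
        _, model, clean, _, _, spec = small_fixture
        cid = model.chain_ids[3]
        cc0 = op.chain_map_cc(clean, model, cid, spec.resolution)
        scaled = sio.DensityMap(clean.grid * 10.0 + 7.0, clean.voxel_size, clean.origin)
        cc1 = op.chain_map_cc(scaled, model, cid, spec.resolution)
        assert cc1 == pytest.approx(cc0, abs=1e-9)

    def test_value_in_unit_interval(self, small_fixture):
        _, model, _, noisy, _, spec = small_fixture
        for cid in model.chain_ids[:10]:
            cc = op.chain_map_cc(noisy, model, cid, spec.resolution)
            assert -1.0 <= cc <= 1.0

    def test_chain_outside_map_raises(self, small_fixture, lattice):
        _, model, clean, _, _, spec = small_fixture
        far = sio.ShellModel(
            {
                "zz": sio.Chain(
                    "zz",
                    np.full((4, 3), 1e4),
                    np.array(["C"] * 4, dtype=object),
                    np.full(4, 1.7),
                )
            }
        )
        with pytest.raises(op.OutOfFrameError):
            op.chain_map_cc(clean, far, "zz", spec.resolution)


class TestClassification:
    @pytest.mark.parametrize(
        "cc,state",
        [
            (0.80, "fully_resolved"),
            (0.60, "less_resolved"),
            (0.75, "less_resolved"),  # strict '>' at the upper threshold
            (0.50, "less_resolved"),  # closed interval at the lower threshold
            (0.49, "absent"),
            (-0.2, "absent"),
        ],
    )
    def test_threshold_conventions(self, cc, state):
        (rec,) = op.classify_chain_states([("A", 0, cc)])
        assert rec.state == state

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            op.classify_chain_states([("A", 0, 0.5)], t_high=0.5, t_low=0.6)

    def test_classify_model_recovers_truth(self, small_fixture, lattice):
        full, model, clean, noisy, plan, spec = small_fixture
        records = op.classify_model(noisy, full, spec.resolution)
        present = {r.site_id for r in records if r.state != "absent"}
        assert present == set(range(60)) - plan


class TestTabulation:
    def test_complete_shell(self, lattice):
        t = op.tabulate_occupancy(lattice, range(60))
        assert t.dimer == {2: 60}
        assert t.trimer == {3: 60}
        assert t.pentamer == {5: 60}
        assert t.all_dimers_complete

    def test_one_dimer_removed_matches_oracle(self, lattice, oracle):
        present = set(range(60)) - set(lattice.group_members("dimer", 0))
        t = op.tabulate_occupancy(lattice, present)
        assert {
            "dimer": t.dimer,
            "trimer": t.trimer,
            "pentamer": t.pentamer,
        } == oracle(lattice, present)

    def test_out_of_range_site_rejected(self, lattice):
        with pytest.raises(ValueError):
            op.tabulate_occupancy(lattice, {61})

    @settings(max_examples=60, deadline=None)
    @given(st.sets(st.integers(0, 59), max_size=60))
    def test_conservation_and_oracle_equivalence(self, lattice, oracle, sites):
        """P1 + P2 on arbitrary subsets."""
        t = op.tabulate_occupancy(lattice, sites)
        for name in ("dimer", "trimer", "pentamer"):
            assert sum(getattr(t, name).values()) == len(sites)
        assert {
            "dimer": t.dimer,
            "trimer": t.trimer,
            "pentamer": t.pentamer,
        } == oracle(lattice, sites)

    def test_group_counts_consistent(self, lattice):
        t = op.tabulate_occupancy(lattice, range(48))
        for name, size in op.CLASS_SIZES.items():
            gc = t.group_counts(name)
            assert sum(k * v for k, v in gc.items()) == 48
            assert t.complete_groups(name) == gc.get(size, 0)

    def test_to_frame_shape(self, lattice):
        frame = op.tabulate_occupancy(lattice, range(50)).to_frame()
        assert list(frame.columns) == ["class", "present_members", "subunits", "groups"]
        assert len(frame) == 2 + 3 + 5


class TestProfiles:
    def test_published_profiles_internally_consistent(self):
        for size, prof in op.PUBLISHED_INTERMEDIATE_PROFILES.items():
            assert prof.n_present == size
            assert sum(prof.trimer.values()) == size
            assert sum(prof.pentamer.values()) == size

    def test_inconsistent_profile_rejected(self):
        with pytest.raises(ValueError):
            op.OccupancyProfile(dimer={2: 4}, trimer={3: 6}, pentamer={5: 5})

    def test_non_multiple_row_rejected(self):
        with pytest.raises(ValueError):
            op.OccupancyProfile(dimer={2: 3}, trimer={3: 3}, pentamer={3: 3})


class TestProfileSearch:
    def test_complete_shell_profile_found(self, lattice):
        prof = op.OccupancyProfile(
            dimer={2: 60}, trimer={3: 60}, pentamer={5: 60}, all_dimers_complete=True
        )
        res = op.find_subset_matching_profile(lattice, prof)
        assert res.status == "found"
        assert res.sites == frozenset(range(60))

    @pytest.mark.parametrize("size", [48, 52, 54])
    def test_published_profile_subsets_exist(self, lattice, size):
        res = op.find_subset_matching_profile(
            lattice, op.PUBLISHED_INTERMEDIATE_PROFILES[size]
        )
        assert res.status == "found"
        table = op.tabulate_occupancy(lattice, res.sites)
        assert table.matches(op.PUBLISHED_INTERMEDIATE_PROFILES[size])
        assert table.all_dimers_complete

    def test_odd_total_is_none(self, lattice):
        prof = op.OccupancyProfile(
            dimer={1: 1, 2: 46}, trimer={1: 2, 3: 45}, pentamer={2: 2, 5: 45}
        )
        res = op.find_subset_matching_profile(lattice, prof)
        assert res.status == "none"

    def test_infeasible_profile_is_none(self, lattice):
        # 20 trimers cannot all be complete with only 54 subunits present
        prof = op.OccupancyProfile(
            dimer={2: 54}, trimer={3: 54}, pentamer={4: 24, 5: 30},
            all_dimers_complete=True,
        )
        res = op.find_subset_matching_profile(lattice, prof)
        assert res.status == "none"

    def test_budget_exhaustion_is_inconclusive(self, lattice):
        res = op.find_subset_matching_profile(
            lattice, op.PUBLISHED_INTERMEDIATE_PROFILES[48], node_budget=10, chunk=5
        )
        assert res.status in ("inconclusive", "found")
        if res.status == "inconclusive":
            assert res.sites is None
            assert not res


class TestDimerOperatorSelection:
    def test_recovers_lattice_pairing_on_synthetic_contact_shell(self, lattice):
        """Build a shell whose only large inter-chain contact is the default
        dimer pairing; contact-based selection must recover that twofold."""
        # place atoms midway towards the dimer partner to create a contact
        spec = ss.SyntheticSpec(seed=3, blob_radius=6.0)
        model = ss.make_reference_shell(lattice, spec)
        bridged = {}
        for cid, ch in model.chains.items():
            site = model.assignment[cid]
            partner = lattice.dimer_partner(site)
            mid = 0.5 * (lattice.centroids[site] + lattice.centroids[partner])
            mid = mid / np.linalg.norm(mid) * spec.shell_radius
            extra = mid[None, :] + np.linspace(-1.5, 1.5, 4)[:, None] * np.array([[0.1, 0.1, 0.1]])
            coords = np.vstack([ch.coords, extra])
            n = len(coords)
            bridged[cid] = sio.Chain(
                cid, coords, np.array(["C"] * n, dtype=object), np.full(n, 1.7)
            )
        bm = sio.ShellModel(bridged, assignment=dict(model.assignment))
        T = op.select_dimer_operator_by_contact(bm, lattice)
        assert np.abs(T - lattice.dimer_operator).max() < 1e-9

    def test_requires_assignment(self, lattice, reference_shell):
        anon = sio.ShellModel(dict(reference_shell.chains))
        with pytest.raises(ValueError):
            op.select_dimer_operator_by_contact(anon, lattice)
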