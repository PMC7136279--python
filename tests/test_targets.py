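"""Artificial target construction: segmentation, mixing, degradation."""

import numpy as np
import pytest

from hdxens.errors import EmptyEnsembleError, InputError
from hdxens.forward import ForwardModelParams, ProtectionFactors, Segment
from hdxens.synthetic import (
    TwoStateSpec,
    generate_toy_trace_ensemble,
    generate_two_state_features,
    uniform_rates,
)
from hdxens.targets import (
    STATE_A,
    STATE_B,
    UNASSIGNED,
    add_noise,
    assign_states,
    build_target,
    make_segments,
    mix_lnP,
    reduce_coverage,
    remove_state_frames,
    residue_segments,
)

from conftest import make_backbone


class TestSegmentation:
    def test_ten_residue_segments_of_310(self):
        segs = make_segments(310, 10)
        assert len(segs) == 34
        assert segs[0] == Segment(1, 10)
        assert segs[1] == Segment(10, 19)
        assert segs[-1] == Segment(298, 310)

    def test_single_segment(self):
        assert make_segments(10, 10) == [Segment(1, 10)]

    def test_one_residue_overlap_and_tail_extension(self):
        for n, L in [(310, 5), (310, 15), (97, 8), (50, 7)]:
            segs = make_segments(n, L)
            for a, b in zip(segs, segs[1:]):
                assert b.start == a.end
            assert segs[0].start == 1
            assert segs[-1].end == n
            covered = set()
            for s in segs:
                covered.update(s.span())
            assert covered == set(range(1, n + 1))

    def test_invalid_length(self):
        with pytest.raises(InputError):
            make_segments(10, 1)
        with pytest.raises(InputError):
            make_segments(10, 11)

    def test_residue_segments_isolate_one_residue(self):
        segs = residue_segments([2, 3, 7])
        assert segs == [Segment(1, 2), Segment(2, 3), Segment(6, 7)]


class TestMixing:
    def _lnp(self, vals):
        return ProtectionFactors(np.arange(2, 2 + len(vals)), np.asarray(vals))

    def test_endpoints_and_hand_value(self):
        a, b = self._lnp([2.0, 4.0]), self._lnp([1.0, 3.0])
        np.testing.assert_allclose(mix_lnP(a, b, 1.0).lnp, a.lnp)
        assert mix_lnP(a, b, 0.6).lnp[0] == pytest.approx(1.6)

    def test_symmetry(self):
        a, b = self._lnp([2.0, 4.0]), self._lnp([1.0, 3.0])
        np.testing.assert_allclose(
            mix_lnP(a, b, 0.3).lnp, mix_lnP(b, a, 0.7).lnp
        )

    def test_bounded_by_inputs(self):
        a, b = self._lnp([2.0, 4.0]), self._lnp([1.0, 3.0])
        m = mix_lnP(a, b, 0.42)
        assert np.all(m.lnp <= np.maximum(a.lnp, b.lnp))
        assert np.all(m.lnp >= np.minimum(a.lnp, b.lnp))

    def test_residue_mismatch(self):
        a = self._lnp([1.0])
        b = ProtectionFactors([9], [1.0])
        with pytest.raises(InputError):
            mix_lnP(a, b, 0.5)


class TestStateAssignment:
    def _ensemble(self):
        topo, xyz = make_backbone(6)
        rng = np.random.default_rng(8)
        ref_a = xyz
        ref_b = xyz + rng.normal(0, 2.0, xyz.shape)
        return topo, ref_a, ref_b

    def test_reference_frames_label_themselves(self):
        from hdxens.io import EnsembleCoordinates
        from scipy.spatial.transform import Rotation

        topo, ref_a, ref_b = self._ensemble()
        rot = Rotation.random(random_state=1).as_matrix()
        far = ref_a + np.random.default_rng(2).normal(0, 5.0, ref_a.shape)
        ens = EnsembleCoordinates(
            np.array([ref_a, ref_b @ rot.T + 3.0, far])
        )
        asg = assign_states(ens, topo, ref_a, ref_b, cutoff=1.0)
        assert asg.labels[0] == STATE_A
        assert asg.labels[1] == STATE_B  # superposition invariance
        assert asg.labels[2] == UNASSIGNED
        assert sum(asg.fractions.values()) == pytest.approx(1.0)


class TestCoverageReduction:
    def test_keep_all(self):
        segs = make_segments(50, 10)
        out = reduce_coverage(segs, np.arange(len(segs)), 1.0)
        assert out == segs

    def test_most_buried_removed_first(self):
        segs = [Segment(10 * i + 1, 10 * i + 10) for i in range(10)]
        scores = np.arange(10, dtype=float)  # seg 9 most buried
        out = reduce_coverage(segs, scores, 0.5, n_residues=100)
        assert out == segs[:5]

    def test_union_coverage_oracle_with_overlaps(self):
        segs = make_segments(60, 10)
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, len(segs))
        out = reduce_coverage(segs, scores, 0.4, n_residues=60)
        covered = set()
        for s in out:
            covered.update(s.span())
        assert len(covered) / 60 <= 0.4
        # adding back the least buried removed segment exceeds the bound
        removed = [s for s in segs if s not in out]
        best_removed = min(removed, key=lambda s: scores[segs.index(s)])
        again = set(covered)
        again.update(best_removed.span())
        # the stopping rule removed only as much as needed: before the last
        # removal coverage was above the threshold
        order = sorted(range(len(segs)),
                       key=lambda i: (-scores[i], segs[i].start))
        kept = list(segs)
        prev_cov = 1.0
        for i in order:
            cov = len({r for s in kept for r in s.span()}) / 60
            if cov <= 0.4:
                break
            prev_cov = cov
            kept = [s for s in kept if s != segs[i]]
        assert prev_cov > 0.4
        assert kept == out

    def test_cannot_remove_everything(self):
        with pytest.raises(InputError):
            reduce_coverage([Segment(1, 10)], [1.0], 0.01, n_residues=100)


class TestNoise:
    def _series(self):
        lnp = ProtectionFactors([2, 3, 4], [1.0, 2.0, 3.0])
        rates = uniform_rates(4, 1.0)
        return build_target(lnp, rates, [Segment(1, 4)], [0.5, 5.0, 50.0])

    def test_zero_sigma_identity_and_seed_determinism(self):
        s = self._series()
        np.testing.assert_array_equal(add_noise(s, 0.0, 1).values, s.values)
        a = add_noise(s, 0.1, seed=42)
        b = add_noise(s, 0.1, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        c = add_noise(s, 0.1, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_empirical_sd_matches_sigma(self):
        lnp = ProtectionFactors(np.arange(2, 102), np.linspace(0.5, 5, 100))
        rates = uniform_rates(101, 1.0)
        clean = build_target(
            lnp, rates, residue_segments(np.arange(2, 102)),
            np.linspace(0.1, 120, 100),
        )
        noisy = add_noise(clean, 0.05, seed=0)
        resid = (noisy.values - clean.values).ravel()
        assert resid.std() == pytest.approx(0.05, rel=0.03)


class TestBuildTarget:
    def test_residue_resolution_reproduces_residue_values(self):
        from hdxens.forward import residue_deuteration

        lnp = ProtectionFactors([2, 3], [1.0, 2.5])
        rates = uniform_rates(3, 1.0)
        series = build_target(lnp, rates, residue_segments([2, 3]), [7.0])
        assert series.values[0, 0] == pytest.approx(
            residue_deuteration(1.0, 1.0, 7.0)
        )
        assert series.values[1, 0] == pytest.approx(
            residue_deuteration(2.5, 1.0, 7.0)
        )

    def test_rows_nondecreasing_over_standard_times(self):
        lnp = ProtectionFactors(np.arange(2, 12), np.linspace(0.2, 6, 10))
        rates = uniform_rates(11, 1.0)
        series = build_target(
            lnp, rates, make_segments(11, 5), [0.167, 1.0, 10.0, 60.0, 120.0]
        )
        assert np.all(np.diff(series.values, axis=1) >= 0)

    def test_regional_beta_override_affects_only_its_segments(self):
        spec = TwoStateSpec(n_frames=60, n_residues=20, seed=6)
        feats, _ = generate_two_state_features(spec)
        rates = uniform_rates(20, 1.0)
        segs = make_segments(20, 5)
        base = ForwardModelParams()
        # "low-error" style override for residues 10-14
        override = ForwardModelParams(
            overrides={r: (0.2, 7.0) for r in range(10, 15)}
        )
        from hdxens.forward import ensemble_lnP
        from hdxens.reweight import EnsembleWeights

        w = EnsembleWeights.uniform(60)
        lnp = ensemble_lnP(feats, w, base)
        plain = build_target(lnp, rates, segs, [1.0, 10.0])
        perturbed = build_target(
            lnp, rates, segs, [1.0, 10.0],
            regional_params=override, features=feats,
        )
        for j, seg in enumerate(segs):
            touched = any(10 <= r <= 14 for r in seg.residues())
            same = np.allclose(plain.values[j], perturbed.values[j])
            assert same != touched


class TestRemoveStateFrames:
    def _assignment(self, rmsd_a):
        n = len(rmsd_a)
        return __import__("hdxens.targets", fromlist=["StateAssignment"]).StateAssignment(
            labels=np.array([UNASSIGNED] * n, dtype=object),
            rmsd_a=np.asarray(rmsd_a, dtype=float),
            rmsd_b=np.full(n, 99.0),
            rmsd_cutoff=1.0,
        )

    def test_known_rmsds(self):
        spec = TwoStateSpec(n_frames=3, n_residues=5, seed=0)
        feats, _ = generate_two_state_features(spec)
        asg = self._assignment([0.5, 1.2, 2.0])
        kept_feats, kept = remove_state_frames(feats, asg, 1.5)
        np.testing.assert_array_equal(kept, [2])
        assert kept_feats.n_frames == 1

    def test_zero_cutoff_removes_nothing(self):
        spec = TwoStateSpec(n_frames=3, n_residues=5, seed=0)
        feats, _ = generate_two_state_features(spec)
        _, kept = remove_state_frames(feats, self._assignment([0.5, 1.2, 2.0]), 0.0)
        assert kept.size == 3

    def test_removing_everything_raises(self):
        spec = TwoStateSpec(n_frames=3, n_residues=5, seed=0)
        feats, _ = generate_two_state_features(spec)
        with pytest.raises(EmptyEnsembleError):
            remove_state_frames(feats, self._assignment([0.5, 1.2, 2.0]), np.inf)
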