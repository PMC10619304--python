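"""Update schedules, noise-square injection, checkpointing and prediction."""

import numpy as np
import pytest

from longimap.trainer import (
    EnsembleMember,
    EnsembleModel,
    TrainConfig,
    ValidationError,
    critic_updates_for_epoch,
    load_ensemble,
    make_noise_square,
    noise_position_for_epoch,
    noise_square_mask,
    predict_map,
    save_ensemble,
    train_personalized,
)
from longimap.volume_io import Volume
from longimap.wgan import GeneratorSpec, build_generator

FULL = TrainConfig()          # the printed 1000-epoch protocol


def tiny_config(epochs=10, seed=0, **kw):
    return TrainConfig(
        epochs=epochs, critic_updates=1, boosted_updates=2,
        boost_first_epochs=2, boost_every=5, gen_levels=3,
        gen_base_features=2, critic_channels=(2, 4), batch_size=2,
        learning_rate=1e-4, seed=seed, **kw)


def tiny_pair(rng, shape=(32, 32, 8)):
    from longimap.volume_io import PatientPair

    base = np.clip(rng.random(shape) * 0.2, 0, 1).astype(np.float32)
    t2 = np.clip(base + 0.1, 0, 1).astype(np.float32)
    return PatientPair(Volume(base), Volume(t2))


class TestCriticUpdateSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 100), (24, 100), (25, 5), (50, 5),
        (99, 100),            # the 100th (1-based) epoch is boosted
        (100, 5), (199, 100), (998, 5), (999, 100),
    ])
    def test_printed_rule(self, epoch, expected):
        assert critic_updates_for_epoch(epoch, FULL) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            critic_updates_for_epoch(1000, FULL)
        with pytest.raises(ValidationError):
            critic_updates_for_epoch(-1, FULL)

    def test_total_updates_match_brute_force(self):
        """Closed accounting over all 1000 epochs vs an explicit loop."""
        total = sum(critic_updates_for_epoch(e, FULL) for e in range(1000))
        brute = 0
        for e1 in range(1, 1001):        # 1-based enumeration
            if e1 <= 25 or e1 % 100 == 0:
                brute += 100
            else:
                brute += 5
        assert total == brute


class TestNoisePositionSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.50), (300, 0.50), (399, 0.50),
        (400, 0.35), (500, 0.35), (599, 0.35),
        (600, 0.65), (799, 0.65),
        (800, None), (850, None), (999, None),
    ])
    def test_phase_boundaries_at_1000_epochs(self, epoch, expected):
        assert noise_position_for_epoch(epoch, FULL) == expected

    def test_invalid_fractions_rejected(self):
        cfg = TrainConfig(noise_change_fractions=(0.6, 0.4))
        with pytest.raises(ValidationError):
            cfg.validate()


class TestNoiseSquare:
    def test_exactly_100_pixels_change(self, rng):
        s = rng.random((64, 64)).astype(np.float32)
        out, mask = make_noise_square(s, 0.5, FULL, np.random.default_rng(0))
        assert mask.sum() == 100
        changed = out != s
        assert changed.sum() == 100
        assert np.array_equal(changed, mask)

    def test_pixels_outside_mask_bitwise_unchanged(self, rng):
        s = rng.random((64, 64)).astype(np.float32)
        out, mask = make_noise_square(s, 0.35, FULL, np.random.default_rng(1))
        assert np.array_equal(out[~mask], s[~mask])

    def test_zero_amplitude_is_identity_with_mask(self, rng):
        cfg = TrainConfig(noise_amplitude=0.0)
        s = rng.random((64, 64)).astype(np.float32)
        out, mask = make_noise_square(s, 0.65, cfg, np.random.default_rng(2))
        assert np.array_equal(out, s)
        assert mask.sum() == 100

    def test_out_of_bounds_position_rejected(self):
        with pytest.raises(ValidationError):
            noise_square_mask((64, 64), 0.02, FULL)


class TestTrainPersonalized:
    def test_four_members_with_scheduled_masks(self, rng):
        cfg = tiny_config(epochs=10)
        ens = train_personalized(tiny_pair(rng), cfg)
        assert len(ens.members) == 4
        for m, frac in zip(ens.members[:3], (0.50, 0.35, 0.65)):
            assert m.noise_mask is not None
            assert np.array_equal(m.noise_mask,
                                  noise_square_mask((32, 32), frac, cfg))
        assert ens.members[3].noise_mask is None

    @pytest.mark.parametrize("epochs", [5, 10, 20])
    def test_member_count_invariant_to_epochs(self, rng, epochs):
        ens = train_personalized(tiny_pair(rng), tiny_config(epochs=epochs))
        assert len(ens.members) == 4

    def test_deterministic_under_seed(self, rng):
        pair = tiny_pair(rng)
        a = train_personalized(pair, tiny_config(epochs=4, seed=11))
        b = train_personalized(pair, tiny_config(epochs=4, seed=11))
        for ma, mb in zip(a.members, b.members):
            for pa, pb in zip(ma.state["params"], mb.state["params"]):
                assert np.array_equal(pa, pb)

    def test_rejects_non_normalized_input(self, rng):
        from longimap.volume_io import PatientPair

        pair = PatientPair(Volume(np.full((32, 32, 4), 3.0, np.float32)),
                           Volume(np.full((32, 32, 4), 3.0, np.float32)))
        with pytest.raises(ValidationError):
            train_personalized(pair, tiny_config())


class TestPredictMap:
    def _ensemble_of(self, members, cfg):
        return EnsembleModel(members, cfg, slice_shape=(32, 32))

    def test_identical_members_equal_single_member(self, rng):
        cfg = tiny_config()
        gen = build_generator(GeneratorSpec(32, 3, 2), np.random.default_rng(5))
        st = gen.state()
        vol = Volume(rng.random((32, 32, 6)).astype(np.float32))
        one = predict_map(self._ensemble_of(
            [EnsembleMember(st, None, 1)], cfg), vol)
        three = predict_map(self._ensemble_of(
            [EnsembleMember(st, None, i) for i in range(3)], cfg), vol)
        assert np.allclose(one.values, three.values, atol=1e-6)

    def test_masked_member_has_zero_weight_on_its_pixels(self, rng):
        """Perturbing a member's output inside its own noise mask must not
        change the ensemble map there."""
        cfg = tiny_config()
        genA = build_generator(GeneratorSpec(32, 3, 2), np.random.default_rng(6))
        genB = build_generator(GeneratorSpec(32, 3, 2), np.random.default_rng(7))
        mask = noise_square_mask((32, 32), 0.5, cfg)
        vol = Volume(rng.random((32, 32, 6)).astype(np.float32))
        base = predict_map(self._ensemble_of(
            [EnsembleMember(genA.state(), mask, 0),
             EnsembleMember(genB.state(), None, 1)], cfg), vol)
        # perturb member A arbitrarily; only its masked pixels must be inert
        for p in genA.params():
            p.value += 0.5
        pert = predict_map(self._ensemble_of(
            [EnsembleMember(genA.state(), mask, 0),
             EnsembleMember(genB.state(), None, 1)], cfg), vol)
        assert np.array_equal(base.values[mask], pert.values[mask])
        assert not np.allclose(base.values[~mask], pert.values[~mask])

    def test_output_shape_matches_input(self, rng):
        cfg = tiny_config()
        ens = train_personalized(tiny_pair(rng), cfg)
        vol = Volume(rng.random((32, 32, 8)).astype(np.float32))
        assert predict_map(ens, vol).shape == (32, 32, 8)

    def test_slice_size_mismatch_rejected(self, rng):
        cfg = tiny_config()
        ens = train_personalized(tiny_pair(rng), cfg)
        with pytest.raises(ValidationError):
            predict_map(ens, Volume(rng.random((16, 16, 4)).astype(np.float32)))


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        ens = train_personalized(tiny_pair(rng), tiny_config(epochs=5))
        save_ensemble(ens, tmp_path / "model")
        back = load_ensemble(tmp_path / "model")
        assert len(back.members) == 4
        vol = Volume(rng.random((32, 32, 6)).astype(np.float32))
        assert np.allclose(predict_map(ens, vol).values,
                           predict_map(back, vol).values)
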