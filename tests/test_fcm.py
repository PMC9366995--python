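import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from nucomp.fcm import (
    CompressorConfig,
    CountTable,
    MixerState,
    ModelSpec,
    best_level_sweep,
    compress_sequence,
    get_level,
    ir_expand,
    level16,
    mix_step,
    symbol_distribution,
    update_model,
)
from oracle import single_model_bits


class TestModelSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"order_k": -1},
            {"order_k": 17},
            {"order_k": 2, "alpha": 0.0},
            {"order_k": 2, "alpha": -1.0},
            {"order_k": 2, "gamma": 1.0},
            {"order_k": 2, "ir_mode": 3},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)

    def test_level16_structure(self):
        cfg = level16()
        assert [m.order_k for m in cfg.models] == [1, 12]
        assert [m.alpha for m in cfg.models] == [1.0, 1.0 / 50.0]
        assert [m.gamma for m in cfg.models] == [0.7, 0.97]
        assert [m.ir_mode for m in cfg.models] == [0, 1]

    def test_ir_override_forces_every_model(self):
        cfg = level16().with_ir_override(2)
        assert all(m.ir_mode == 2 for m in cfg.effective_models())
        # the underlying spec list is untouched
        assert [m.ir_mode for m in cfg.models] == [0, 1]


class TestSymbolDistribution:
    def test_empty_table_uniform(self):
        table = CountTable(order_k=2)
        assert np.allclose(symbol_distribution(table, 0, alpha=1.0), 0.25)

    def test_single_symbol_counts(self):
        table = CountTable(order_k=2)
        for _ in range(3):
            table.increment(5, 0)
        p = symbol_distribution(table, 5, alpha=1.0)
        assert p[0] == pytest.approx(4 / 7)
        assert np.allclose(p[1:], 1 / 7)

    def test_small_alpha_sharpens(self):
        table = CountTable(order_k=1)
        table.increment(2, 0)
        p = symbol_distribution(table, 2, alpha=1 / 50)
        assert p[0] == pytest.approx(1.02 / 1.08)
        assert p.sum() == pytest.approx(1.0)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            symbol_distribution(CountTable(order_k=1), 0, alpha=0.0)


class TestIrExpand:
    def test_examples(self):
        # k=2, window (A,C,G): ir word (C,G,T) -> context CG, symbol T
        assert ir_expand([0, 1, 2]) == ((1 << 2) | 2, 3)
        # k=2, window (A,T,A): ir word (T,A,T) -> context TA, symbol T
        assert ir_expand([0, 3, 0]) == ((3 << 2) | 0, 3)

    def test_involution_over_all_windows(self):
        """Re-expanding the reverse complement recovers the forward pair."""
        for window in itertools.product(range(4), repeat=3):
            fwd_ctx = (window[0] << 2) | window[1]
            fwd_sym = window[2]
            rc_window = [3 - b for b in reversed(window)]
            assert ir_expand(rc_window) == (fwd_ctx, fwd_sym)


class TestUpdateModel:
    def _counts(self, table):
        return {ctx: tuple(c[:4]) for ctx, c in table.counts.items()}

    def test_mode0_forward_only(self):
        table = update_model(CountTable(2), [0, 1, 2], ir_mode=0)
        assert self._counts(table) == {(0 << 2) | 1: (0, 0, 1, 0)}

    def test_mode2_reverse_complement_only(self):
        table = update_model(CountTable(2), [0, 1, 2], ir_mode=2)
        assert self._counts(table) == {(1 << 2) | 2: (0, 0, 0, 1)}

    def test_mode1_both_in_same_table(self):
        table = update_model(CountTable(2), [0, 1, 2], ir_mode=1)
        counts = self._counts(table)
        assert counts[(0 << 2) | 1] == (0, 0, 1, 0)
        assert counts[(1 << 2) | 2] == (0, 0, 0, 1)
        assert sum(sum(v) for v in counts.values()) == 2


class TestMixStep:
    def test_equal_predictions_keep_weights(self):
        preds = [np.full(4, 0.25), np.full(4, 0.25)]
        state = MixerState(np.array([0.5, 0.5]))
        p_mix, new = mix_step(preds, state, [0.9, 0.9], observed=2)
        assert np.allclose(p_mix, 0.25)
        assert np.allclose(new.weights, 0.5)

    def test_direct_substitution(self):
        preds = [np.array([0.8, 0.1, 0.05, 0.05]), np.array([0.2, 0.4, 0.2, 0.2])]
        state = MixerState(np.array([0.5, 0.5]))
        _, new = mix_step(preds, state, [1.0, 1.0], observed=0)
        assert np.allclose(new.weights, [0.8, 0.2])

    def test_gamma_zero_forgets_history(self):
        preds = [np.array([0.8, 0.1, 0.05, 0.05]), np.array([0.2, 0.4, 0.2, 0.2])]
        state = MixerState(np.array([0.99, 0.01]))
        _, new = mix_step(preds, state, [0.0, 0.0], observed=0)
        assert np.allclose(new.weights, [0.8, 0.2])

    def test_mixture_is_convex(self):
        preds = [np.array([0.7, 0.1, 0.1, 0.1]), np.array([0.1, 0.1, 0.1, 0.7])]
        state = MixerState(np.array([0.25, 0.75]))
        p_mix, new = mix_step(preds, state, [0.9, 0.9], observed=3)
        assert p_mix.sum() == pytest.approx(1.0, abs=1e-9)
        assert new.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestCompressSequence:
    def test_first_symbol_costs_two_bits(self, k1_config, lvl16):
        for seq in ("A", "CGT", "TTTT"):
            for cfg in (k1_config, lvl16):
                assert compress_sequence(seq, cfg).per_symbol_bits[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("n", [10, 100, 500])
    def test_homopolymer_closed_form(self, k1_config, n):
        """A run of n identical bases costs log2((n+1)(n+2)(n+3)/6) bits."""
        res = compress_sequence("A" * n, k1_config)
        expected = math.log2((n + 1) * (n + 2) * (n + 3) / 6)
        assert res.total_bits == pytest.approx(expected, abs=1e-9)

    def test_total_equals_per_symbol_sum(self, lvl16):
        res = compress_sequence("ACGTACGTTTGGACCA" * 20, lvl16)
        assert res.total_bits == pytest.approx(res.per_symbol_bits.sum(), rel=1e-9)
        assert np.all(res.per_symbol_bits >= 0)

    def test_deterministic(self, lvl16):
        seq = "ACGTTGCA" * 50
        a = compress_sequence(seq, lvl16)
        b = compress_sequence(seq, lvl16)
        assert a.total_bits == b.total_bits
        assert np.array_equal(a.per_symbol_bits, b.per_symbol_bits)

    def test_rejects_unsanitized_input(self, lvl16):
        with pytest.raises(ValueError, match="sanitize"):
            compress_sequence("ACGN", lvl16)

    def test_rejects_empty(self, lvl16):
        with pytest.raises(ValueError):
            compress_sequence("", lvl16)

    def test_oracle_agreement_on_random_sequences(self, k1_config):
        """Spot-check against the independent accumulator (full sweep is in
        the acceptance suite)."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            assert compress_sequence(seq, k1_config).total_bits == pytest.approx(
                single_model_bits(seq, k=1, alpha=1.0), abs=1e-9
            )

    def test_oracle_agreement_higher_order(self):
        cfg = CompressorConfig((ModelSpec(order_k=3, alpha=0.5, gamma=0.9),), label="k3")
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        assert compress_sequence(seq, cfg).total_bits == pytest.approx(
            single_model_bits(seq, k=3, alpha=0.5), abs=1e-6
        )

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_bits_nonnegative_and_conserved(self, seq):
        res = compress_sequence(seq, level16())
        assert np.all(res.per_symbol_bits >= 0)
        assert res.total_bits == pytest.approx(res.per_symbol_bits.sum(), rel=1e-9)


class TestBestLevelSweep:
    def _homopolymer_records(self, n=10):
        return [make_record(f"h{i}", "ACGT"[i % 4] * 200) for i in range(n)]

    def test_single_config_always_wins(self, lvl16):
        summary = best_level_sweep(self._homopolymer_records(3), [lvl16])
        assert summary.best_frequency == {"level16": 1.0}

    def test_tie_goes_to_lowest_index(self, lvl16):
        # identical mixtures under different labels tie on every record
        twin = CompressorConfig(lvl16.models, label="twin")
        summary = best_level_sweep(self._homopolymer_records(4), [lvl16, twin])
        assert summary.best_frequency["level16"] == 1.0
        assert summary.best_frequency["twin"] == 0.0

    def test_superset_mixture_wins_on_repetitive_records(self, k1_config, lvl16):
        """level16 (k=1 model plus a deep model) beats the bare k=1 model on
        every homopolymer fixture."""
        summary = best_level_sweep(self._homopolymer_records(10), [k1_config, lvl16])
        assert summary.best_frequency["level16"] == 1.0
        assert summary.nc_sum["level16"] < summary.nc_sum["k1"]

    def test_nc_sum_accumulates_over_records(self, k1_config):
        recs = self._homopolymer_records(2)
        single = [compress_sequence(r.residues, k1_config).nc for r in recs]
        summary = best_level_sweep(recs, [k1_config])
        assert summary.nc_sum["k1"] == pytest.approx(sum(single))

    def test_builtin_levels_resolvable(self):
        for name in ("level16", "order4", "order8"):
            assert get_level(name).label == name
        with pytest.raises(KeyError):
            get_level("nope")
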