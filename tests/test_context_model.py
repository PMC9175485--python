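"""Row-mean quantization, adaptive statistics, composite contexts, entropy."""

from __future__ import annotations

import math

import numpy as np
import pytest

from acoqs import container
from acoqs.context_model import (
    AdaptiveModel,
    BASE_SENTINEL,
    compute_row_mean,
    conditional_entropy,
    decode_with_contexts,
    encode_sequence,
    make_context,
    quality_context_indices,
    quantize_row_mean,
    row_bin_index,
    row_bin_values,
)
from acoqs.metrics import report_from_container
from acoqs.range_coder import RangeDecoder, RangeEncoder
from acoqs.scan_order import serpentine_path
from acoqs.synthetic import generate, preset


class TestRowMean:
    @pytest.mark.parametrize("quals,expected", [
        ([30, 32, 34], 32.0),
        ([40], 40.0),
        ([0, 0, 0, 0], 0.0),
        ([], 0.0),
    ])
    def test_mean(self, quals, expected):
        assert compute_row_mean(quals) == expected

    @pytest.mark.parametrize("q,expected", [
        (29, 30), (31, 32), (33, 34), (37, 38),   # one per 2-wide bin
        (40.2, 40),                                # pass-through, rounded
        (0, 30), (29.999, 30), (30, 32), (38, 38), (41, 41),
    ])
    def test_quantization_rule(self, q, expected):
        assert quantize_row_mean(q) == expected

    def test_bin_values_cover_all_outputs(self):
        vals = row_bin_values(41)
        assert vals == [30, 32, 34, 36, 38, 39, 40, 41]
        for q in np.linspace(0, 41, 500):
            assert quantize_row_mean(float(q)) in vals
        assert row_bin_index(41)[30] == 0


class TestAdaptiveModel:
    def test_fresh_context_predicts_uniform(self):
        m = AdaptiveModel(64)
        p = m.predict("k")
        assert np.allclose(p, 1 / 64)
        assert math.isclose(p.sum(), 1.0)

    def test_single_observation_count_arithmetic(self):
        m = AdaptiveModel(64, increment=32)
        m.update("k", 40)
        assert m.predict("k")[40] == pytest.approx(33 / 96)
        assert m.counts("k")[40] == 33

    def test_totals_never_exceed_rescale_limit(self):
        m = AdaptiveModel(8, increment=32, rescale_limit=256)
        for i in range(500):
            m.update("k", i % 8)
            t = m._table("k")
            assert t[8] <= 256
            assert min(t[:8]) >= 1

    def test_predicted_distribution_converges_to_source(self):
        rng = np.random.default_rng(5)
        truth = np.array([0.55, 0.25, 0.12, 0.05, 0.02, 0.01])
        m = AdaptiveModel(6, increment=8, rescale_limit=8192)
        for s in rng.choice(6, size=10_000, p=truth):
            m.update("k", int(s))
        tv = 0.5 * np.abs(m.predict("k") - truth).sum()
        assert tv <= 0.05

    def test_hot_loops_match_adaptive_model_arithmetic(self):
        """encode_sequence / decode_with_contexts inline the same count
        update as AdaptiveModel; their tables must agree state-for-state."""
        rng = np.random.default_rng(9)
        alphabet, n = 12, 3000
        ctxs = rng.integers(0, 5, n).tolist()
        syms = rng.integers(0, alphabet, n).tolist()
        enc = RangeEncoder()
        tables = encode_sequence(enc, ctxs, syms, alphabet,
                                 increment=16, rescale_limit=512)
        ref = AdaptiveModel(alphabet, increment=16, rescale_limit=512)
        for c, s in zip(ctxs, syms):
            ref.update(c, s)
        assert tables == ref.tables
        dec_tables: dict = {}
        back = decode_with_contexts(RangeDecoder(enc.getvalue()), ctxs, alphabet,
                                    increment=16, rescale_limit=512,
                                    tables=dec_tables)
        assert back == syms
        assert dec_tables == ref.tables

    def test_stationary_stream_codes_near_source_entropy(self):
        rng = np.random.default_rng(17)
        probs = np.array([0.4, 0.3, 0.15, 0.08, 0.04, 0.03])
        n = 200_000
        syms = rng.choice(6, size=n, p=probs).tolist()
        enc = RangeEncoder()
        encode_sequence(enc, [0] * n, syms, 6)
        rate = len(enc.getvalue()) * 8 / n
        entropy = -sum(p * math.log2(p) for p in probs)
        assert rate <= entropy + 0.05


class TestMakeContext:
    def test_block_start_uses_sentinels(self):
        path = serpentine_path([3, 3])
        rows = [np.array([40, 40, 40]), np.array([40, 40, 40])]
        bases = ["ACG", "TTA"]
        bins = [40, 40]
        key = make_context(0, path, rows, bases, bins)
        assert key.q_prev1 == 0 and key.q_prev2_coarse == 0
        assert key.base_cur == 0          # 'A'
        assert key.base_prev == BASE_SENTINEL

    def test_third_cell_sees_full_and_coarse_history(self):
        path = serpentine_path([3, 3])
        rows = [np.array([40, 40, 40]), np.array([40, 40, 40])]
        key = make_context(2, path, rows, ["ACG", "TTA"], [40, 40])
        assert key.q_prev1 == 40
        assert key.q_prev2_coarse == 8    # 40 // 5

    def test_out_of_range_position_rejected(self):
        path = serpentine_path([2])
        with pytest.raises(IndexError):
            make_context(4, path, [np.array([1, 2])], ["AC"], [30])

    def test_vectorized_indices_match_reference_construction(self):
        """The codec's vectorized context indices equal the scalar reference
        keys on a random ragged block (the decodability contract)."""
        rng = np.random.default_rng(21)
        lengths = rng.integers(0, 15, size=12)
        qmax, q2_div = 41, 5
        rows = [rng.integers(0, qmax + 1, size=ln) for ln in lengths]
        bases = ["".join(rng.choice(list("ACGTN"), size=ln)) for ln in lengths]
        bin_map = row_bin_index(qmax)
        bins = [quantize_row_mean(compute_row_mean(q)) for q in rows]
        bin_idx = np.array([bin_map[b] for b in bins])

        path = serpentine_path(lengths)
        lmax = int(lengths.max())
        q_mat = np.zeros((len(rows), lmax), dtype=np.int64)
        for i, q in enumerate(rows):
            q_mat[i, :q.size] = q
        syms = q_mat[path.rows, path.cols]
        cfg = container.CodecConfig()
        stride, bp_size, q2_levels = container._quality_schema(cfg, qmax, True, len(bin_map))
        bf = container._fold_block(bases, lengths, lmax)
        static = container._static_contexts(cfg, True, path, bin_idx, bf, bp_size)
        ctxs = quality_context_indices(syms, static, stride, q2_levels, q2_div)

        n_bases = 6
        for i in range(len(path)):
            key = make_context(i, path, rows, bases, bins, q2_div)
            expected = ((key.q_prev1 * q2_levels + key.q_prev2_coarse) * stride
                        + bin_map[key.row_bin] * bp_size
                        + key.base_cur * n_bases + key.base_prev)
            assert ctxs[i] == expected


class TestConditionalEntropy:
    def test_independent_condition_leaves_entropy_unchanged(self):
        # X uniform over 2 symbols in every condition
        joint = np.array([[5, 5], [20, 20], [3, 3]])
        assert conditional_entropy(joint) == pytest.approx(1.0)

    def test_deterministic_function_gives_zero(self):
        joint = np.array([[7, 0], [0, 11]])
        assert conditional_entropy(joint) == 0.0

    def test_hand_evaluated_two_by_two(self):
        joint = np.array([[2, 1], [1, 2]])
        h = -(2 / 3 * math.log2(2 / 3) + 1 / 3 * math.log2(1 / 3))
        assert conditional_entropy(joint) == pytest.approx(h)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            conditional_entropy(np.zeros((2, 2)))

    def test_base_pair_context_lowers_entropy_on_dip_data(self):
        """With base-change dips, H(X | cur,prev base) <= H(X | cur base)."""
        recs = generate(preset("dips-only", n_reads=800, read_len=60, seed=3))
        x, j1, j2 = [], [], []
        code = {b: i for i, b in enumerate("ACGTN")}
        for r in recs:
            for c in range(len(r)):
                x.append(int(r.quals[c]))
                j1.append(code[r.bases[c]])
                j2.append(code[r.bases[c - 1]] if c else 5)
        x = np.array(x); j1 = np.array(j1); j2 = np.array(j2)

        def joint(ctx):
            nc, nx = ctx.max() + 1, x.max() + 1
            m = np.zeros((nc, nx))
            np.add.at(m, (ctx, x), 1)
            return m

        h2 = conditional_entropy(joint(j1 * 6 + j2))
        h1 = conditional_entropy(joint(j1))
        assert h2 <= h1
        assert h2 < h1 - 0.01  # the dip structure is actually informative


class TestRowMeanBenefit:
    def test_row_mean_context_pays_for_its_side_stream(self):
        """With per-read mean spread >= 4 Phred, enabling the row-mean
        context shrinks the total quality-attributable output."""
        recs = generate(preset("row-spread", n_reads=4000, read_len=80, seed=7))

        def total(row_mean):
            cfg = container.CodecConfig(embed_bases=False, row_mean=row_mean)
            return report_from_container(container.compress(recs, cfg)).l_after

        assert total("on") < total("off")
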