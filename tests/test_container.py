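"""End-to-end container round trips, negative controls, file-level API."""

from __future__ import annotations

import numpy as np
import pytest

from acoqs.container import (
    CodecConfig,
    ContainerError,
    compress,
    compress_file,
    decompress,
    decompress_file,
    stream_sizes,
    verify_file,
)
from acoqs.fastq_io import FastqRecord, read_fastq, write_fastq
from acoqs.metrics import report_from_container
from acoqs.synthetic import generate, preset

from conftest import random_records


def _roundtrip(records, cfg=None, external=None):
    blob = compress(records, cfg)
    quals, bases = decompress(blob, external_bases=external)
    assert len(quals) == len(records)
    for q, r in zip(quals, records):
        assert np.array_equal(q, r.quals), "quality stream not reproduced"
    return blob, bases


class TestBasics:
    def test_empty_input_round_trips_to_empty(self):
        blob, bases = _roundtrip([])
        assert bases == []
        assert len(blob) < 64  # header + checksum only

    def test_single_constant_read_compresses_below_raw(self):
        rec = FastqRecord("r", "A" * 200, np.full(200, 35, dtype=np.uint8))
        blob, _ = _roundtrip([rec], CodecConfig(embed_bases=False, row_mean="off"),
                             external=[rec.bases])
        assert report_from_container(blob).l_after < 200

    def test_embedded_bases_are_reproduced(self, rng):
        records = random_records(rng, 40)
        _, bases = _roundtrip(records, CodecConfig(embed_bases=True))
        assert bases == [r.bases for r in records]

    def test_fifty_thousand_quality_values_round_trip(self):
        records = generate(preset("paper-like", n_reads=500, read_len=100, seed=1))
        _roundtrip(records, CodecConfig(embed_bases=False),
                   external=[r.bases for r in records])


@pytest.mark.parametrize("cfg", [
    CodecConfig(),
    CodecConfig(block_size=7),
    CodecConfig(scan="raster"),
    CodecConfig(row_mean="on"),
    CodecConfig(row_mean="off", base_context=False, use_prev2=False),
    CodecConfig(embed_bases=False),
    CodecConfig(increment=4, rescale_limit=1024, q2_div=8),
], ids=["default", "multiblock", "raster", "rowmean-on", "order1", "nobases",
        "alt-hyper"])
class TestRoundTripConfigurations:
    def test_adversarial_random_files(self, cfg, rng):
        """Ragged lengths, empty reads, N bases, extreme quality values."""
        for _ in range(6):
            records = random_records(rng, int(rng.integers(0, 30)))
            external = None if cfg.embed_bases else [r.bases for r in records]
            _roundtrip(records, cfg, external)


class TestEdgeShapes:
    @pytest.mark.parametrize("quals", [
        [[0]], [[93]], [[0, 93, 0, 93]], [[5], [], [7, 7]],
    ])
    def test_extreme_and_degenerate_reads(self, quals):
        records = [FastqRecord(f"r{i}", "A" * len(q),
                               np.array(q, dtype=np.uint8))
                   for i, q in enumerate(quals)]
        _roundtrip(records)

    def test_length_one_reads_many_blocks(self, rng):
        records = [FastqRecord(f"r{i}", "C", np.array([i % 42], dtype=np.uint8))
                   for i in range(57)]
        _roundtrip(records, CodecConfig(block_size=10))


class TestNegativeControls:
    def test_flipped_payload_byte_is_detected(self, rng):
        records = random_records(rng, 20, allow_empty=False)
        blob = bytearray(compress(records))
        blob[len(blob) // 2] ^= 0x10
        with pytest.raises((ContainerError, EOFError, IndexError)):
            decompress(bytes(blob))

    def test_wrong_external_bases_fail_the_checksum(self, rng):
        records = random_records(rng, 15, allow_empty=False, n_prob=0.0)
        cfg = CodecConfig(embed_bases=False)
        blob = compress(records, cfg)
        wrong = ["T" * len(r.bases) for r in records]
        with pytest.raises(ContainerError):
            decompress(blob, external_bases=wrong)

    def test_missing_external_bases_rejected(self, rng):
        records = random_records(rng, 5, allow_empty=False)
        blob = compress(records, CodecConfig(embed_bases=False))
        with pytest.raises(ContainerError, match="bases"):
            decompress(blob)

    def test_bad_magic_rejected(self):
        blob = bytearray(compress([]))
        blob[:4] = b"WHAT"
        with pytest.raises(ContainerError, match="magic"):
            decompress(bytes(blob))

    def test_unknown_version_rejected(self):
        blob = bytearray(compress([]))
        blob[4] = 99
        with pytest.raises(ContainerError, match="version"):
            decompress(bytes(blob))

    def test_truncated_container_rejected(self, rng):
        blob = compress(random_records(rng, 10))
        with pytest.raises((ContainerError, EOFError)):
            decompress(blob[:len(blob) // 2])

    def test_quality_above_alphabet_rejected_at_compress(self):
        rec = FastqRecord("r", "A", np.array([94], dtype=np.uint8))
        with pytest.raises(ValueError):
            compress([rec])


class TestStreamSizes:
    def test_parts_sum_to_total(self, rng):
        records = random_records(rng, 30, allow_empty=False)
        blob = compress(records, CodecConfig(block_size=11))
        sizes = stream_sizes(blob)
        assert (sizes["header"] + sizes["lengths"] + sizes["rowbin"]
                + sizes["bases"] + sizes["quality"] + sizes["checksum"]
                + sizes["overhead"]) == sizes["total"] == len(blob)


class TestDirectionOfEffect:
    def test_serpentine_compound_beats_raster_order1(self):
        """The full scheme produces a smaller quality stream than a raster
        scan with a single previous-quality context on structured data."""
        records = generate(preset("paper-like", n_reads=5000, read_len=100, seed=1))

        def qual_size(cfg):
            return report_from_container(compress(records, cfg)).l_after

        full = qual_size(CodecConfig(embed_bases=False))
        baseline = qual_size(CodecConfig(embed_bases=False, scan="raster",
                                         row_mean="off", base_context=False,
                                         use_prev2=False))
        assert full < baseline


class TestFileLevel:
    def test_compress_decompress_verify_files(self, tmp_path, rng):
        records = random_records(rng, 25, allow_empty=False)
        src = tmp_path / "in.fastq"
        write_fastq(records, src)
        cont = tmp_path / "out.aco"
        ids = tmp_path / "ids.txt"
        compress_file(src, cont, ids_path=ids)
        assert verify_file(src, cont)

        out = tmp_path / "back.fastq"
        decompress_file(cont, out, ids_path=ids)
        back = list(read_fastq(out))
        assert [r.identifier for r in back] == [r.identifier for r in records]
        assert [r.bases for r in back] == [r.bases for r in records]
        assert all(np.array_equal(a.quals, b.quals)
                   for a, b in zip(back, records))

    def test_external_bases_file_round_trip(self, tmp_path, rng):
        records = random_records(rng, 10, allow_empty=False)
        src = tmp_path / "in.fastq"
        write_fastq(records, src)
        cont = tmp_path / "out.aco"
        compress_file(src, cont, CodecConfig(embed_bases=False))
        out = tmp_path / "back.fastq"
        decompress_file(cont, out, bases_path=src)
        back = list(read_fastq(out))
        assert all(np.array_equal(a.quals, b.quals)
                   for a, b in zip(back, records))
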