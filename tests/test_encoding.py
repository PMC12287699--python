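"""One-hot codec, batching, row shuffling and the record container."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selcnn.encoding import (
    EncodingError,
    RecordFormatError,
    decode_tensor,
    encode_msa,
    encode_record,
    make_batches,
    pad_batch,
    read_records,
    record_count,
    shuffle_rows,
    write_records,
)
from selcnn.seqio import Msa

from conftest import random_example


def test_bit_patterns():
    """A:00001 C:00010 G:00100 T:01000 -:10000 (channels gap,T,G,C,A)."""
    msa = Msa(rows=[("s1", "ACGT-N")])
    # pad to codon structure with a second row? length 6 is divisible by 3
    ex = encode_msa(msa, label=1)
    expect = {
        0: [0, 0, 0, 0, 1],  # A
        1: [0, 0, 0, 1, 0],  # C
        2: [0, 0, 1, 0, 0],  # G
        3: [0, 1, 0, 0, 0],  # T
        4: [1, 0, 0, 0, 0],  # -
        5: [0, 0, 0, 0, 0],  # N -> all-zero
    }
    for j, bits in expect.items():
        assert ex.tensor[0, j].tolist() == bits


def test_all_gap_column_sets_gap_channel_everywhere():
    msa = Msa(rows=[("a", "---"), ("b", "---")])
    ex = encode_msa(msa, label=0)
    assert np.all(ex.tensor[:, :, 0] == 1)
    assert np.all(ex.tensor[:, :, 1:] == 0)


def test_length_not_divisible_by_three_rejected():
    with pytest.raises(Exception):
        encode_msa(Msa(rows=[("a", "ACGT")]), label=0)


def test_encode_decode_round_trip(small_gene_records, rng):
    for rec in small_gene_records:
        ex = encode_record(rec)
        decoded = decode_tensor(ex.tensor, names=rec.leaf_names)
        assert decoded.rows == rec.alignment_rows
    for _ in range(20):
        ex = random_example(rng, length=9)
        decoded = decode_tensor(ex.tensor)
        assert decode_tensor(encode_msa(decoded, 0).tensor).rows == decoded.rows


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    rows=st.integers(2, 8),
    codons_=st.integers(1, 20),
    data=st.data(),
)
def test_encode_decode_identity_property(rows, codons_, data):
    """decode(encode(msa)) == msa for arbitrary gapped codon MSAs."""
    length = 3 * codons_
    alphabet = "ACGT-"
    seqs = [
        data.draw(st.text(alphabet=alphabet, min_size=length, max_size=length))
        for _ in range(rows)
    ]
    msa = Msa(rows=[(f"t{i + 1}", s) for i, s in enumerate(seqs)])
    ex = encode_msa(msa, label=1)
    assert decode_tensor(ex.tensor).rows == msa.rows


def test_all_zero_decodes_to_n():
    t = np.zeros((1, 3, 5), dtype=np.uint8)
    assert decode_tensor(t).rows[0][1] == "NNN"


def test_two_hot_rejected():
    t = np.zeros((1, 3, 5), dtype=np.uint8)
    t[0, 0, 0] = t[0, 0, 1] = 1
    with pytest.raises(EncodingError):
        decode_tensor(t)


def test_padding_arithmetic(rng):
    exs = [random_example(rng, length=l) for l in (30, 60, 90)]
    batch = pad_batch(exs)
    assert batch.tensors.shape == (3, 8, 90, 5)
    assert np.all(batch.tensors[0, :, 30:] == 0)
    assert np.all(batch.tensors[1, :, 60:] == 0)
    # padding is all-zero, distinct from the gap channel
    assert batch.tensors[0, :, 30:, 0].sum() == 0


def test_batch_reshuffling_differs_across_epochs(rng):
    exs = [random_example(rng, length=30, gene_id=f"g{i}") for i in range(64)]
    ids1 = [b.gene_ids for b in make_batches(exs, 16, rng=np.random.default_rng(1))]
    ids2 = [b.gene_ids for b in make_batches(exs, 16, rng=np.random.default_rng(2))]
    assert ids1 != ids2
    assert sorted(sum(ids1, [])) == sorted(sum(ids2, []))


def test_empty_example_set_rejected():
    with pytest.raises(ValueError):
        list(make_batches([], 4))


def test_shuffle_rows_preserves_row_multiset(rng):
    ex = random_example(rng, length=30, label=1)
    shuffled = shuffle_rows(ex, np.random.default_rng(3))
    assert shuffled.label == ex.label
    orig = {ex.tensor[i].tobytes() for i in range(8)}
    new = {shuffled.tensor[i].tobytes() for i in range(8)}
    assert orig == new


def test_record_round_trip(tmp_path, rng):
    exs = [
        random_example(rng, length=3 * rng.integers(5, 20), label=int(rng.integers(2)),
                       gene_id=f"gene{i}")
        for i in range(10)
    ]
    path = tmp_path / "data.records"
    assert write_records(exs, path) == 10
    assert record_count(path) == 10
    back = list(read_records(path))
    assert len(back) == 10
    for a, b in zip(exs, back):
        assert a.gene_id == b.gene_id
        assert a.label == b.label
        assert np.array_equal(a.tensor, b.tensor)


def test_truncated_record_file_detected(tmp_path, rng):
    exs = [random_example(rng, length=30, gene_id=f"g{i}") for i in range(5)]
    path = tmp_path / "data.records"
    write_records(exs, path)
    data = path.read_bytes()
    (tmp_path / "cut.records").write_bytes(data[: len(data) - 100])
    with pytest.raises(RecordFormatError, match="truncated"):
        list(read_records(tmp_path / "cut.records"))


def test_version_mismatch_detected(tmp_path, rng):
    path = tmp_path / "data.records"
    write_records([random_example(rng, length=30)], path)
    data = bytearray(path.read_bytes())
    data[8] = 99  # version field
    path.write_bytes(bytes(data))
    with pytest.raises(RecordFormatError, match="version"):
        list(read_records(path))


def test_streaming_read_is_lazy(tmp_path, rng):
    """Reading yields examples one at a time without materializing the file."""
    exs = [random_example(rng, length=30, gene_id=f"g{i}") for i in range(50)]
    path = tmp_path / "data.records"
    write_records(exs, path)
    stream = read_records(path)
    first = next(stream)
    assert first.gene_id == "g0"
    # generator: no list allocated, remaining items still pending
    assert sum(1 for _ in stream) == 49
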