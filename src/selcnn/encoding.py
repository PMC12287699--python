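"""One-hot alignment encoding, batching and a streamable record format.

Each alignment character maps to a five-channel bit pattern (channel order
gap, T, G, C, A — i.e. A:00001, C:00010, G:00100, T:01000, -:10000 reading
bits left to right).  The ambiguity character N encodes as all-zero, which is
also the padding value: padding never collides with a real character because
the gap has its own channel.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import Msa
from .simulate import GeneRecord

#: channel index per character; bit patterns read left-to-right as channels 0..4
CHANNELS = {"-": 0, "T": 1, "G": 2, "C": 3, "A": 4}
N_CHANNELS = 5
_DECODE = {v: k for k, v in CHANNELS.items()}


class EncodingError(ValueError):
    pass


class RecordFormatError(ValueError):
    pass


@dataclass
class EncodedExample:
    """One alignment as an n x L x 5 binary tensor with its label."""

    tensor: np.ndarray  # uint8, shape (n, L, 5)
    label: int
    gene_id: str = ""

    @property
    def n_taxa(self) -> int:
        return self.tensor.shape[0]

    @property
    def length(self) -> int:
        return self.tensor.shape[1]


@dataclass
class Batch:
    tensors: np.ndarray  # float64, shape (B, n, Lmax, 5); zero beyond true length
    labels: np.ndarray  # float64, shape (B,)
    lengths: np.ndarray  # int, true L per example
    gene_ids: list[str]


def encode_msa(msa: Msa, label: int, gene_id: str = "") -> EncodedExample:
    """One-hot encode an MSA (rows in given order) into an n x L x 5 tensor."""
    msa.require_codon_structure()
    n, length = msa.n_rows, msa.n_columns
    tensor = np.zeros((n, length, N_CHANNELS), dtype=np.uint8)
    for i, (_, seq) in enumerate(msa.rows):
        for j, ch in enumerate(seq):
            if ch == "N":
                continue  # ambiguity: all-zero channels
            try:
                tensor[i, j, CHANNELS[ch]] = 1
            except KeyError:
                raise EncodingError(
                    f"cannot encode character {ch!r} at row {i}, column {j}"
                ) from None
    return EncodedExample(tensor=tensor, label=int(label), gene_id=gene_id)


def encode_record(record: GeneRecord, use_true_alignment: bool = True) -> EncodedExample:
    """Encode a simulated gene's true alignment."""
    if not use_true_alignment:
        raise ValueError("only true-alignment encoding is available here; "
                         "align externally and use encode_msa")
    msa = Msa(rows=record.alignment_rows)
    return encode_msa(msa, record.label, gene_id=record.gene_id)


def decode_tensor(
    tensor: np.ndarray, names: Sequence[str] | None = None
) -> Msa:
    """Invert encode_msa; all-zero positions decode to ``N``."""
    tensor = np.asarray(tensor)
    if tensor.ndim != 3 or tensor.shape[2] != N_CHANNELS:
        raise EncodingError(f"expected an (n, L, 5) tensor, got shape {tensor.shape}")
    hot = tensor.sum(axis=2)
    if np.any(hot > 1):
        i, j = np.argwhere(hot > 1)[0]
        raise EncodingError(f"multiple hot channels at row {i}, column {j}")
    n, length = tensor.shape[:2]
    if names is None:
        names = [f"t{i + 1}" for i in range(n)]
    rows = []
    idx = tensor.argmax(axis=2)
    for i in range(n):
        chars = [
            _DECODE[int(idx[i, j])] if hot[i, j] else "N" for j in range(length)
        ]
        rows.append((names[i], "".join(chars)))
    return Msa(rows=rows)


def shuffle_rows(example: EncodedExample, rng: np.random.Generator) -> EncodedExample:
    """Independently permute the taxon rows (tree-information ablation)."""
    perm = rng.permutation(example.n_taxa)
    return EncodedExample(
        tensor=example.tensor[perm], label=example.label, gene_id=example.gene_id
    )


def pad_batch(examples: Sequence[EncodedExample]) -> Batch:
    """Stack examples, zero-padding columns to the longest alignment."""
    if not examples:
        raise ValueError("cannot build a batch from an empty example list")
    n = examples[0].n_taxa
    if any(e.n_taxa != n for e in examples):
        raise EncodingError("all examples in a batch must share the taxon count")
    lengths = np.array([e.length for e in examples])
    lmax = int(lengths.max())
    tensors = np.zeros((len(examples), n, lmax, N_CHANNELS), dtype=np.float64)
    for k, e in enumerate(examples):
        tensors[k, :, : e.length] = e.tensor
    labels = np.array([e.label for e in examples], dtype=np.float64)
    return Batch(
        tensors=tensors,
        labels=labels,
        lengths=lengths,
        gene_ids=[e.gene_id for e in examples],
    )


def make_batches(
    examples: Sequence[EncodedExample],
    batch_size: int = 512,
    shuffle: bool = True,
    shuffle_rows_flag: bool = False,
    rng: np.random.Generator | None = None,
) -> Iterator[Batch]:
    """Partition examples into zero-padded batches, reshuffled per call."""
    if not examples:
        raise ValueError("empty example set")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    order = rng.permutation(len(examples)) if shuffle else np.arange(len(examples))
    for start in range(0, len(examples), batch_size):
        chunk = [examples[i] for i in order[start : start + batch_size]]
        if shuffle_rows_flag:
            chunk = [shuffle_rows(e, rng) for e in chunk]
        yield pad_batch(chunk)


# ---------------------------------------------------------------------------
# record container: versioned header + length-prefixed records, streamable

_MAGIC = b"SELCNNR\x00"
_VERSION = 1
_HEADER = struct.Struct("<8sIIQ")  # magic, version, n_taxa, count
_REC_HEAD = struct.Struct("<HBI")  # gene_id length, label, L


def write_records(examples: Iterable[EncodedExample], path: str | Path) -> int:
    """Serialize examples; returns the number written."""
    path = Path(path)
    count = 0
    n_taxa = 0
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, 0, 0))  # placeholder header
        for ex in examples:
            if count == 0:
                n_taxa = ex.n_taxa
            elif ex.n_taxa != n_taxa:
                raise RecordFormatError("mixed taxon counts in one record file")
            gid = ex.gene_id.encode()
            fh.write(_REC_HEAD.pack(len(gid), ex.label, ex.length))
            fh.write(gid)
            fh.write(np.ascontiguousarray(ex.tensor, dtype=np.uint8).tobytes())
            count += 1
        fh.seek(0)
        fh.write(_HEADER.pack(_MAGIC, _VERSION, n_taxa, count))
    return count


def read_records(path: str | Path) -> Iterator[EncodedExample]:
    """Stream examples back without loading the whole file."""
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise RecordFormatError("truncated record file (no header)")
        magic, version, n_taxa, count = _HEADER.unpack(head)
        if magic != _MAGIC:
            raise RecordFormatError("not a selcnn record file")
        if version != _VERSION:
            raise RecordFormatError(
                f"record file version {version} unsupported (expected {_VERSION})"
            )
        for k in range(count):
            rec_head = fh.read(_REC_HEAD.size)
            if len(rec_head) < _REC_HEAD.size:
                raise RecordFormatError(
                    f"truncated record file: {k} of {count} records read"
                )
            gid_len, label, length = _REC_HEAD.unpack(rec_head)
            gid = fh.read(gid_len).decode()
            payload = fh.read(n_taxa * length * N_CHANNELS)
            if len(payload) < n_taxa * length * N_CHANNELS:
                raise RecordFormatError(
                    f"truncated record file: {k} of {count} records read"
                )
            tensor = np.frombuffer(payload, dtype=np.uint8).reshape(
                n_taxa, length, N_CHANNELS
            )
            yield EncodedExample(tensor=tensor.copy(), label=label, gene_id=gid)
        if fh.read(1):
            raise RecordFormatError("trailing bytes after final record")


def record_count(path: str | Path) -> int:
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise RecordFormatError("truncated record file (no header)")
        magic, _, _, count = _HEADER.unpack(head)
        if magic != _MAGIC:
            raise RecordFormatError("not a selcnn record file")
        return count
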