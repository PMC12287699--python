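"""Sequence/alignment I/O, codon translation and optional aligner adapters."""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import STOP_CODONS, translate_codon

NT_ALPHABET = set("ACGTN-")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")


class FormatError(ValueError):
    pass


class InvalidSequenceError(ValueError):
    pass


class AlignerNotFoundError(RuntimeError):
    """Raised when an optional external aligner executable is absent."""


class AlignerError(RuntimeError):
    pass


@dataclass
class Msa:
    """An alignment: ordered (taxon, gapped sequence) rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        names = [name for name, _ in self.rows]
        if len(set(names)) != len(names):
            raise FormatError("duplicate row labels in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.rows]

    def require_codon_structure(self) -> None:
        if self.n_columns % 3 != 0:
            raise FormatError(
                f"codon MSA length {self.n_columns} is not divisible by 3"
            )

    def reordered(self, names: list[str]) -> "Msa":
        by_name = dict(self.rows)
        missing = [n for n in names if n not in by_name]
        if missing:
            raise FormatError(f"alignment is missing taxa: {missing}")
        return Msa(rows=[(n, by_name[n]) for n in names])


def read_fasta(path: str | Path, alphabet: str | None = "nt") -> list[tuple[str, str]]:
    """Read FASTA records as (label, uppercased sequence) pairs.

    Raises FormatError on empty files, duplicate labels, or characters
    outside the requested alphabet ("nt", "aa" or None to skip the check).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    allowed = {"nt": NT_ALPHABET, "aa": AA_ALPHABET, None: None}[alphabet]
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA label {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if allowed is not None:
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"record {rec.id!r} contains invalid characters {sorted(bad)}"
                )
        out.append((rec.id, seq))
    return out


def read_fasta_msa(path: str | Path, alphabet: str | None = "nt") -> Msa:
    return Msa(rows=read_fasta(path, alphabet=alphabet))


def write_fasta(records: list[tuple[str, str]] | Msa, path: str | Path) -> None:
    """Write records 60-column wrapped; inverse of read_fasta on its output."""
    rows = records.rows if isinstance(records, Msa) else records
    bio = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in rows
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def translate_codons(nt_sequence: str) -> str:
    """Translate a (possibly gapped) codon sequence to amino acids.

    The gap codon ``---`` maps to ``-``.  Internal stop codons and lengths
    not divisible by 3 raise InvalidSequenceError.
    """
    seq = nt_sequence.upper()
    if len(seq) % 3 != 0:
        raise InvalidSequenceError(
            f"sequence length {len(seq)} is not divisible by 3"
        )
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise InvalidSequenceError(
                f"internal stop codon {codon} at nucleotide position {i}"
            )
        try:
            out.append(translate_codon(codon))
        except ValueError as exc:
            raise InvalidSequenceError(str(exc)) from exc
    return "".join(out)


def backtranslate_alignment(
    aa_msa: Msa, nt_sequences: dict[str, str] | list[tuple[str, str]]
) -> Msa:
    """Replace each aligned amino acid by its source codon (gap -> ``---``).

    For every taxon the ungapped amino-acid row must equal the translation of
    its unaligned nucleotide sequence; mismatches raise InvalidSequenceError
    naming the taxon and position.
    """
    nt = dict(nt_sequences)
    rows = []
    for name, aa_row in aa_msa.rows:
        if name not in nt:
            raise InvalidSequenceError(f"no nucleotide sequence for taxon {name!r}")
        source = nt[name].upper()
        expected = translate_codons(source)
        stripped = aa_row.replace("-", "")
        if stripped != expected:
            pos = next(
                (k for k, (a, b) in enumerate(zip(stripped, expected)) if a != b),
                min(len(stripped), len(expected)),
            )
            raise InvalidSequenceError(
                f"taxon {name!r}: aligned protein disagrees with translation "
                f"at amino-acid position {pos}"
            )
        codons_iter = iter(
            source[i : i + 3] for i in range(0, len(source), 3)
        )
        rows.append(
            (name, "".join("---" if a == "-" else next(codons_iter) for a in aa_row))
        )
    return Msa(rows=rows)


_ALIGNERS = {
    "clustalo": ["clustalo", "--infile", "{in}", "--outfile", "{out}", "--force"],
    "mafft": ["mafft", "--auto", "{in}"],
    "prank-aa": ["prank", "-d={in}", "-o={stem}", "-protein", "-once"],
    "prank-codon": ["prank", "-d={in}", "-o={stem}", "-codon", "-once"],
}

#: tools fed amino acids (results are back-translated); prank-codon gets nucleotides
_AA_TOOLS = {"clustalo", "mafft", "prank-aa"}


def run_external_aligner(
    tool: str,
    sequences: list[tuple[str, str]],
    workdir: str | Path | None = None,
) -> Msa:
    """Align unaligned coding sequences with an optional external tool.

    Amino-acid tools receive translated sequences and the resulting protein
    alignment is back-translated to codons; the codon-model tool is fed
    nucleotides directly.  A missing executable raises AlignerNotFoundError
    (the default pipeline then falls back to true alignments).
    """
    if tool not in _ALIGNERS:
        raise ValueError(f"unknown aligner {tool!r}; choose from {sorted(_ALIGNERS)}")
    executable = _ALIGNERS[tool][0]
    if shutil.which(executable) is None:
        raise AlignerNotFoundError(
            f"optional dependency absent: {executable!r} not found on PATH"
        )

    own_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp(prefix="selcnn_align_")) if own_tmp else Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    try:
        if tool in _AA_TOOLS:
            payload = [(name, translate_codons(seq)) for name, seq in sequences]
        else:
            payload = sequences
        infile = workdir / "input.fasta"
        outfile = workdir / "aligned.fasta"
        write_fasta(payload, infile)
        cmd = [
            part.format(**{"in": str(infile), "out": str(outfile), "stem": str(workdir / "pranked")})
            for part in _ALIGNERS[tool]
        ]
        capture_stdout = tool == "mafft"
        result = subprocess.run(cmd, capture_output=True, text=True)
        if result.returncode != 0:
            raise AlignerError(
                f"{tool} exited with status {result.returncode}:\n{result.stderr}"
            )
        if capture_stdout:
            outfile.write_text(result.stdout)
        elif tool.startswith("prank"):
            candidates = sorted(workdir.glob("pranked.best.fas"))
            if not candidates:
                raise AlignerError(f"{tool} produced no output alignment")
            outfile = candidates[0]
        msa = read_fasta_msa(outfile, alphabet="aa" if tool in _AA_TOOLS else "nt")
        if tool in _AA_TOOLS:
            msa = backtranslate_alignment(msa, sequences)
        msa = msa.reordered([name for name, _ in sequences])
        msa.require_codon_structure()
        return msa
    finally:
        if own_tmp:
            shutil.rmtree(workdir, ignore_errors=True)
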