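"""DNA sequence I/O and the 2-bit packed representation.

The repeat models keep the whole already-coded sequence addressable, so bases
are packed four to a byte (A=0, C=1, G=2, T=3).  Base ``j`` occupies bits
``[2*(j % 4), 2*(j % 4) + 1]`` of byte ``j // 4`` (least-significant first),
e.g. ``"ACGT"`` packs to the single byte ``0xE4``.

Input alphabets are truncated to ACGT: lowercase is folded to uppercase and
every other character (N, IUPAC ambiguity codes, gaps) is deleted.  The codec
is therefore lossless with respect to the filtered ACGT stream only; a
:class:`FilterReport` tells the caller how many characters were dropped.
Multi-record FASTA files are concatenated in file order; record boundaries,
headers, case and N-runs are not preserved.  All coordinates are 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_CODE = (3, 2, 1, 0)  # A<->T, C<->G

# byte-value -> base code, 255 for "not a base" (lowercase folded first)
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in CODE.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_WEIGHTS = np.array([1, 4, 16, 64], dtype=np.uint8)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of alphabet truncation: ``kept + removed`` equals the raw
    residue count after stripping FASTA headers and whitespace."""

    kept: int
    removed: int
    source_name: str = ""


class PackedSequence:
    """Immutable 2-bit-per-base DNA sequence.

    Parameters
    ----------
    codes
        uint8 array of base codes in 0..3.
    """

    __slots__ = ("length", "data")

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.size and codes.max(initial=0) > 3:
            raise ValueError("base codes must be in 0..3")
        self.length = int(codes.size)
        pad = (-self.length) % 4
        padded = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
        quads = padded.reshape(-1, 4)
        self.data = (quads * _WEIGHTS).sum(axis=1).astype(np.uint8).tobytes()

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PackedSequence)
            and self.length == other.length
            and self.data == other.data
        )

    def __hash__(self):
        return hash((self.length, self.data))

    def get(self, i: int) -> int:
        """Base code at 0-based position ``i``."""
        if not 0 <= i < self.length:
            raise IndexError(i)
        return (self.data[i // 4] >> (2 * (i % 4))) & 3

    def codes(self) -> np.ndarray:
        """Unpacked uint8 array of base codes (length ``len(self)``)."""
        raw = np.frombuffer(self.data, dtype=np.uint8)
        shifts = np.arange(4, dtype=np.uint8) * 2
        quads = (raw[:, None] >> shifts[None, :]) & 3
        return quads.reshape(-1)[: self.length].copy()

    def __str__(self) -> str:
        return unpack(self)


def pack(s: str) -> PackedSequence:
    """Pack an ACGT string; rejects any other character."""
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = _LUT[arr]
    bad = codes > 3
    if bad.any():
        ch = chr(arr[int(np.argmax(bad))])
        raise ValueError(f"non-ACGT character {ch!r} in sequence")
    return PackedSequence(codes)


def unpack(p: PackedSequence) -> str:
    return "".join(BASES[c] for c in p.codes())


def filter_codes(raw: bytes, source_name: str = "") -> tuple[np.ndarray, FilterReport]:
    """Map raw residue bytes to base codes, deleting non-ACGT characters."""
    arr = np.frombuffer(raw, dtype=np.uint8)
    codes = _LUT[arr]
    keep = codes <= 3
    kept = codes[keep]
    return kept, FilterReport(
        kept=int(keep.sum()), removed=int(arr.size - keep.sum()), source_name=source_name
    )


def read_sequence(
    path: Union[str, Path], format: str = "fasta"
) -> tuple[PackedSequence, FilterReport]:
    """Read a DNA sequence from FASTA or raw text, truncated to ACGT.

    FASTA records are concatenated in file order.  Raises ``ValueError`` for a
    malformed FASTA (no ``>`` header) or for input that is empty after
    filtering.
    """
    path = Path(path)
    if format == "fasta":
        text = path.read_text()
        if not text.lstrip().startswith(">"):
            raise ValueError(f"{path}: not a FASTA file (no '>' header)")
        parts = [str(rec.seq) for rec in SeqIO.parse(io.StringIO(text), "fasta")]
        raw = "".join(parts).encode("ascii")
    elif format == "raw":
        raw = b"".join(path.read_bytes().split())
    else:
        raise ValueError(f"unknown format {format!r}")
    codes, report = filter_codes(raw, source_name=path.name)
    if codes.size == 0:
        raise ValueError(f"{path}: no ACGT bases after filtering")
    return PackedSequence(codes), report


def write_sequence(
    p: PackedSequence,
    path: Union[str, Path],
    format: str = "fasta",
    line_width: int = 70,
    header: str = "cpdna",
) -> None:
    """Write a sequence as a single FASTA record or as raw text."""
    s = unpack(p)
    path = Path(path)
    if format == "fasta":
        if line_width < 1:
            raise ValueError("line_width must be >= 1")
        body = "\n".join(s[i : i + line_width] for i in range(0, len(s), line_width))
        path.write_text(f">{header}\n{body}\n")
    elif format == "raw":
        path.write_text(s)
    else:
        raise ValueError(f"unknown format {format!r}")


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def reverse_complement(s: str) -> str:
    return unpack(PackedSequence(reverse_complement_codes(pack(s).codes())))
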