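"""Residue alphabets and one-hot encoding of fixed-length amino acid sequences.

A sequence of common length ``T`` over an alphabet of ``n`` residue symbols
plus one padding symbol is represented as an ``(n + 1) x T`` binary matrix:
one row per symbol (padding row first), one column per position, exactly one
active row per column.  The padding symbol is ``"0"`` by convention, the one
character guaranteed never to appear in an amino acid sequence.

By default the padding symbol owns a dedicated row (index 0), so every
column — padded positions included — sums to one and encoding is exactly
invertible.  The alternative convention, padded positions as all-zero
columns, is available through ``pad_row=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholders used by UniProt: selenocysteine (U), pyrrolysine (O),
#: Asx (B), Glx (Z) and unknown (X).
EXTENDED_SYMBOLS = "UOBZX"

DEFAULT_RESIDUES = STANDARD_AMINO_ACIDS + EXTENDED_SYMBOLS
DEFAULT_PAD = "0"


class CodecError(ValueError):
    """Invalid alphabet, sequence or one-hot matrix."""


@dataclass
class Alphabet:
    """Ordered residue symbol set plus a padding symbol.

    Index 0 is always the padding symbol; residues take indices ``1..n`` in
    the given order.  ``n`` counts residue symbols only, so one-hot matrices
    have ``n + 1`` rows.
    """

    residue_symbols: tuple[str, ...]
    pad_symbol: str = DEFAULT_PAD
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.residue_symbols = tuple(self.residue_symbols)
        if not self.residue_symbols:
            raise CodecError("alphabet needs at least one residue symbol")
        if len(set(self.residue_symbols)) != len(self.residue_symbols):
            dupes = sorted(
                s for s in set(self.residue_symbols)
                if self.residue_symbols.count(s) > 1
            )
            raise CodecError(f"duplicate residue symbols: {dupes}")
        if any(len(s) != 1 for s in self.residue_symbols) or len(self.pad_symbol) != 1:
            raise CodecError("symbols must be single characters")
        if self.pad_symbol in self.residue_symbols:
            raise CodecError(
                f"pad symbol {self.pad_symbol!r} collides with a residue symbol"
            )
        self._index = {self.pad_symbol: 0}
        for i, s in enumerate(self.residue_symbols, start=1):
            self._index[s] = i

    @property
    def n(self) -> int:
        """Number of residue symbols (excluding the pad symbol)."""
        return len(self.residue_symbols)

    @property
    def size(self) -> int:
        """Total number of one-hot rows, ``n + 1``."""
        return self.n + 1

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise CodecError(f"symbol {symbol!r} not in alphabet") from None

    def symbol(self, index: int) -> str:
        if index == 0:
            return self.pad_symbol
        if 1 <= index <= self.n:
            return self.residue_symbols[index - 1]
        raise CodecError(f"index {index} outside 0..{self.n}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def indices(self, seq: str) -> np.ndarray:
        """Vector of symbol indices for ``seq``, reporting bad positions."""
        out = np.empty(len(seq), dtype=np.int64)
        for j, ch in enumerate(seq):
            idx = self._index.get(ch)
            if idx is None:
                raise CodecError(f"unknown character {ch!r} at position {j}")
            out[j] = idx
        return out


def build_alphabet(residues, pad: str = DEFAULT_PAD) -> Alphabet:
    """Build an :class:`Alphabet` with deterministic index assignment.

    The pad symbol gets index 0 and the residues indices ``1..n`` in the
    order given.
    """
    return Alphabet(tuple(residues), pad)


def default_alphabet() -> Alphabet:
    """The 25-symbol alphabet: 20 standard amino acids plus U, O, B, Z, X."""
    return build_alphabet(DEFAULT_RESIDUES)


def encode_one_hot(seq: str, alphabet: Alphabet, pad_row: bool = True) -> np.ndarray:
    """Encode a (padded) symbol string as an ``(n + 1) x T`` binary matrix.

    Column ``j`` has a single one at the row of ``seq[j]``.  With
    ``pad_row=False`` padded positions become all-zero columns instead of
    activating row 0.
    """
    idx = alphabet.indices(seq)
    mat = np.zeros((alphabet.size, len(seq)), dtype=np.uint8)
    mat[idx, np.arange(len(seq))] = 1
    if not pad_row:
        mat[0, :] = 0
    return mat


def decode_one_hot(matrix: np.ndarray, alphabet: Alphabet, pad_row: bool = True) -> str:
    """Invert :func:`encode_one_hot`; reject malformed columns."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != alphabet.size:
        raise CodecError(
            f"expected {alphabet.size} rows (symbols x positions), got shape {matrix.shape}"
        )
    sums = matrix.sum(axis=0)
    expected = 1 if pad_row else None
    out = []
    for j in range(matrix.shape[1]):
        s = sums[j]
        if s == 0:
            if pad_row:
                raise CodecError(f"column {j} has no active row")
            out.append(alphabet.pad_symbol)
            continue
        if s > 1:
            raise CodecError(f"column {j} has {int(s)} active rows")
        out.append(alphabet.symbol(int(np.argmax(matrix[:, j]))))
    del expected
    return "".join(out)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs (uppercased)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path, width: int = 60) -> None:
    """Write ``(id, sequence)`` or ``(id, description, sequence)`` records."""
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 3:
                rid, desc, seq = rec
                header = f">{rid} {desc}" if desc else f">{rid}"
            else:
                rid, seq = rec
                header = f">{rid}"
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def save_one_hot(matrix: np.ndarray, alphabet: Alphabet, path) -> None:
    """Save a one-hot matrix as ``.npy`` with a JSON sidecar.

    The sidecar records symbol order (pad first) and orientation so the
    array is self-describing.
    """
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(matrix, dtype=np.uint8))
    sidecar = {
        "symbols": [alphabet.pad_symbol, *alphabet.residue_symbols],
        "pad_symbol": alphabet.pad_symbol,
        "T": int(matrix.shape[1]),
        "orientation": "symbols_x_positions",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_one_hot(path) -> tuple[np.ndarray, Alphabet]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["orientation"] != "symbols_x_positions":
        raise CodecError(f"unsupported orientation {meta['orientation']!r}")
    alphabet = build_alphabet(meta["symbols"][1:], meta["pad_symbol"])
    return np.load(path.with_suffix(".npy")), alphabet
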