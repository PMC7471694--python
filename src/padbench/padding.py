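"""Seven padding strategies bringing sequences to a common length ``T``.

Dense paddings keep the pad symbols in one contiguous block:

* ``post`` — pad symbols appended after the sequence,
* ``pre``  — pad symbols prepended before the sequence,
* ``mid``  — a single pad block inserted in the middle,
* ``ext``  — the pad split evenly between both ends.

Sparse paddings intersperse pad symbols or resample residues:

* ``strf`` — pad symbols distributed uniformly along the sequence
  (residue ``i`` lands at index ``floor(i*T/L)``),
* ``rnd``  — pad positions drawn uniformly at random (seeded),
* ``zoom`` — no pad symbols at all; contiguous residues are repeated,
  output position ``j`` holding input residue ``floor(j*L/T)``.

``aug`` is the augmentation scheme: one sequence represented by all seven
single-mode paddings at once (see :func:`augment`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .codec import DEFAULT_PAD

#: The seven single padding modes, in canonical order.
SINGLE_MODES = ("post", "pre", "mid", "ext", "strf", "rnd", "zoom")

#: All mode names accepted by configuration surfaces (``aug`` = augmentation).
ALL_MODES = SINGLE_MODES + ("aug",)

DENSE_MODES = frozenset({"post", "pre", "mid", "ext"})
SPARSE_MODES = frozenset({"strf", "rnd", "zoom"})


class PaddingError(ValueError):
    """Sequence/configuration combination that cannot be padded."""


@dataclass(frozen=True)
class PaddingConfig:
    """Target length, mode and RNG seed (the seed only matters for rnd)."""

    T: int = 1000
    mode: str = "post"
    seed: int = 0
    pad_symbol: str = DEFAULT_PAD

    def __post_init__(self) -> None:
        if self.T < 1:
            raise PaddingError(f"target length must be >= 1, got {self.T}")
        if self.mode not in ALL_MODES:
            raise PaddingError(f"unknown padding mode {self.mode!r}; choose from {ALL_MODES}")


@dataclass(frozen=True)
class PaddedSequence:
    """A length-``T`` symbol string with provenance.

    ``residue_positions`` lists, in input order, the output indices holding
    the original residues; for ``zoom`` it is instead the monotone map
    giving the input index behind each output position.
    """

    symbols: str
    source_id: str
    L: int
    mode: str
    residue_positions: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.symbols)


def _rnd_rng(seed: int, source_id: str) -> np.random.Generator:
    # Per-sequence stream so augmentation and re-runs are stable regardless
    # of processing order.
    tag = zlib.crc32(source_id.encode()) & 0xFFFFFFFF
    return np.random.default_rng([seed & 0xFFFFFFFF, tag])


def _pad_positions(L: int, T: int, mode: str, rng: np.random.Generator | None) -> list[int]:
    """Output indices of the original residues, in order (modes != zoom)."""
    Z = T - L
    if mode == "post":
        return list(range(L))
    if mode == "pre":
        return list(range(Z, T))
    if mode == "mid":
        head = -(-L // 2)  # ceil(L/2) residues before the zero block
        return list(range(head)) + list(range(head + Z, T))
    if mode == "ext":
        lead = Z // 2  # extra zero goes to the right
        return list(range(lead, lead + L))
    if mode == "strf":
        return [(i * T) // L for i in range(L)] if L else []
    if mode == "rnd":
        pads = set(rng.choice(T, size=Z, replace=False).tolist()) if Z else set()
        return [j for j in range(T) if j not in pads]
    raise PaddingError(f"unknown mode {mode!r}")


def pad(seq: str, config: PaddingConfig, source_id: str = "") -> PaddedSequence:
    """Pad ``seq`` (length ``L <= T``) to the common length per ``config``.

    Deterministic given ``(seq, config, source_id)``; the rnd mode derives a
    per-sequence stream from ``(config.seed, source_id)``.  Sequences longer
    than ``T`` are rejected — filter or :func:`truncate` first.
    """
    if config.mode == "aug":
        raise PaddingError("mode 'aug' expands to seven variants; use augment()")
    L, T = len(seq), config.T
    if L > T:
        raise PaddingError(f"sequence of length {L} exceeds target length {T}")
    if config.pad_symbol in seq:
        raise PaddingError(f"sequence already contains the pad symbol {config.pad_symbol!r}")

    if config.mode == "zoom":
        if L == 0:
            raise PaddingError("cannot zoom an empty sequence")
        index_map = [(j * L) // T for j in range(T)]
        symbols = "".join(seq[i] for i in index_map)
        return PaddedSequence(symbols, source_id, L, "zoom", tuple(index_map))

    rng = _rnd_rng(config.seed, source_id) if config.mode == "rnd" else None
    positions = _pad_positions(L, T, config.mode, rng)
    out = [config.pad_symbol] * T
    for ch, j in zip(seq, positions):
        out[j] = ch
    return PaddedSequence("".join(out), source_id, L, config.mode, tuple(positions))


def truncate(seq: str, T: int, side: str = "tail") -> str:
    """Cut ``seq`` to at most ``T`` residues.

    ``side="tail"`` (default) drops the tail, keeping the first ``T``
    residues; ``side="head"`` drops the head, keeping the last ``T``.
    """
    if side not in ("head", "tail"):
        raise PaddingError(f"side must be 'head' or 'tail', got {side!r}")
    if len(seq) <= T:
        return seq
    return seq[:T] if side == "tail" else seq[len(seq) - T:]


def augment(seq: str, T: int, seed: int = 0, source_id: str = "",
            pad_symbol: str = DEFAULT_PAD) -> dict[str, PaddedSequence]:
    """Represent one sequence by all seven single-mode paddings.

    Returns a mode-keyed mapping; each variant equals the corresponding
    :func:`pad` output under the same seed and shares ``source_id``.
    """
    return {
        mode: pad(seq, PaddingConfig(T=T, mode=mode, seed=seed, pad_symbol=pad_symbol),
                  source_id=source_id)
        for mode in SINGLE_MODES
    }


def classify_mode(mode: str) -> str:
    """Class of a padding mode: ``dense``, ``sparse`` or ``augmented``."""
    if mode in DENSE_MODES:
        return "dense"
    if mode in SPARSE_MODES:
        return "sparse"
    if mode == "aug":
        return "augmented"
    raise PaddingError(f"unknown padding mode {mode!r}")
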