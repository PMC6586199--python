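"""Base and codon one-hot encodings of DNA fragments.

Two numeric views of every fragment feed the two network paths:

* the base one-hot matrix (BOH): one 4-bit row per base of the forward
  strand followed by one row per base of the reverse complement, so a
  length-``L`` sequence yields a ``2L x 4`` matrix with the letter map
  A=[0,0,0,1], C=[0,0,1,0], G=[0,1,0,0], T=[1,0,0,0];
* the codon one-hot matrix (COH): the sequence is expanded into six
  reading frames (three offsets on each strand), every complete codon
  becomes a 64-bit one-hot row, giving ``2(L-2) x 64`` for ``L >= 3``.

Ambiguous letters (N and any other IUPAC code) produce all-zero rows
rather than errors. Codon columns are ordered lexicographically over
A < C < G < T (AAA=0 ... TTT=63).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Base -> column index of the single 1 bit in its 4-vector.
#: A=[0,0,0,1], C=[0,0,1,0], G=[0,1,0,0], T=[1,0,0,0].
_BASE_ONEHOT_COL = {"A": 3, "C": 2, "G": 1, "T": 0}

#: Base -> integer 0..3 in lexicographic order, used for codon indices.
_BASE_LEX = {"A": 0, "C": 1, "G": 2, "T": 3}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Fragment-length cap per model group; padded inputs have 2*L_max rows.
GROUP_MAX_LEN = {"A": 400, "B": 800, "C": 1200}

#: Closed fragment-length range per simulation group (D = long contigs).
GROUP_LENGTH_RANGES = {
    "A": (100, 400),
    "B": (400, 800),
    "C": (800, 1200),
    "D": (5000, 10000),
}

# lookup tables over raw byte values for vectorised encoding
_LEX_LUT = np.full(256, -1, dtype=np.int8)
for _b, _v in _BASE_LEX.items():
    _LEX_LUT[ord(_b)] = _v

_ONEHOT_COL_LUT = np.full(256, -1, dtype=np.int8)
for _b, _v in _BASE_ONEHOT_COL.items():
    _ONEHOT_COL_LUT[ord(_b)] = _v

_COMP_LUT = np.full(256, ord("N"), dtype=np.uint8)
for _b, _v in _COMPLEMENT.items():
    _COMP_LUT[ord(_b)] = ord(_v)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string.

    A<->T and C<->G; every other letter maps to N.
    """
    if not seq:
        raise ValueError("cannot reverse-complement an empty sequence")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COMP_LUT[raw][::-1].tobytes().decode("ascii")


def _seq_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def base_index_track(seq: str) -> np.ndarray:
    """Per-row one-hot column index for the BOH matrix; -1 marks ambiguous.

    Length is ``2L``: forward strand rows then reverse-complement rows.
    """
    if not seq:
        raise ValueError("empty sequence")
    fwd = _ONEHOT_COL_LUT[_seq_bytes(seq)]
    rc = _ONEHOT_COL_LUT[_seq_bytes(reverse_complement(seq))]
    return np.concatenate([fwd, rc]).astype(np.int16)


def codon_index_track(seq: str) -> np.ndarray:
    """Per-row column index for the COH matrix; -1 marks codons with
    ambiguous bases.

    Rows follow the fixed frame order: forward offsets 0, 1, 2, then
    reverse-complement offsets 0, 1, 2; each frame contributes its
    complete codons only. Total length is ``2(L-2)``.
    """
    length = len(seq)
    if length < 3:
        raise ValueError(f"need at least 3 bases to form a codon, got {length}")
    out: list[np.ndarray] = []
    for strand in (seq, reverse_complement(seq)):
        lex = _LEX_LUT[_seq_bytes(strand)].astype(np.int16)
        for offset in range(3):
            frame = lex[offset : offset + 3 * ((length - offset) // 3)]
            trip = frame.reshape(-1, 3)
            idx = trip[:, 0] * 16 + trip[:, 1] * 4 + trip[:, 2]
            idx[(trip < 0).any(axis=1)] = -1
            out.append(idx)
    return np.concatenate(out)


def encode_boh(seq: str) -> np.ndarray:
    """Base one-hot matrix, shape ``(2L, 4)``, dtype uint8."""
    idx = base_index_track(seq)
    mat = np.zeros((idx.shape[0], 4), dtype=np.uint8)
    valid = idx >= 0
    mat[np.nonzero(valid)[0], idx[valid]] = 1
    return mat


def expand_codon_frames(seq: str) -> list[list[str]]:
    """Split a sequence into 6 codon lists: forward frames at offsets
    0, 1, 2 then reverse-complement frames at offsets 0, 1, 2.

    Trailing bases that cannot complete a codon are discarded, so the
    total codon count is ``2(L-2)`` for ``L >= 3``.
    """
    length = len(seq)
    if length < 3:
        raise ValueError(f"need at least 3 bases to form a codon, got {length}")
    frames = []
    for strand in (seq, reverse_complement(seq)):
        for offset in range(3):
            frames.append(
                [strand[i : i + 3] for i in range(offset, length - 2, 3)]
            )
    return frames


def codon_index(codon: str) -> int | None:
    """Lexicographic index of a 3-mer over A<C<G<T; None if ambiguous."""
    if len(codon) != 3:
        raise ValueError(f"codon must have 3 bases, got {codon!r}")
    try:
        return (
            _BASE_LEX[codon[0]] * 16 + _BASE_LEX[codon[1]] * 4 + _BASE_LEX[codon[2]]
        )
    except KeyError:
        return None


def encode_coh(seq: str) -> np.ndarray:
    """Codon one-hot matrix, shape ``(2(L-2), 64)``, dtype uint8."""
    idx = codon_index_track(seq)
    mat = np.zeros((idx.shape[0], 64), dtype=np.uint8)
    valid = idx >= 0
    mat[np.nonzero(valid)[0], idx[valid]] = 1
    return mat


@dataclass
class PaddedEncoding:
    """Fixed-shape pair of encodings for one fragment within a group.

    Both matrices are zero-padded along rows to ``2 * L_max`` of the
    group, with padding appended after the data rows.
    """

    boh: np.ndarray
    coh: np.ndarray
    group: str
    original_length: int


def pad_for_group(boh: np.ndarray, coh: np.ndarray, group: str) -> PaddedEncoding:
    if group not in GROUP_MAX_LEN:
        raise ValueError(f"unknown group {group!r}")
    rows = 2 * GROUP_MAX_LEN[group]
    length = boh.shape[0] // 2
    if boh.shape[0] > rows:
        raise ValueError(
            f"fragment of length {length} exceeds group {group} maximum "
            f"{GROUP_MAX_LEN[group]}"
        )
    return PaddedEncoding(
        boh=_pad_rows(boh, rows),
        coh=_pad_rows(coh, rows),
        group=group,
        original_length=length,
    )


def _pad_rows(mat: np.ndarray, rows: int) -> np.ndarray:
    if mat.shape[0] == rows:
        return mat
    out = np.zeros((rows, mat.shape[1]), dtype=mat.dtype)
    out[: mat.shape[0]] = mat
    return out


def encode_batch(seqs: list[str], group: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack padded BOH/COH encodings for a batch of sequences.

    Returns float32 arrays of shape ``(n, 2*L_max, 4)`` and
    ``(n, 2*L_max, 64)`` ready for the network.
    """
    rows = 2 * GROUP_MAX_LEN[group]
    n = len(seqs)
    boh = np.zeros((n, rows, 4), dtype=np.float32)
    coh = np.zeros((n, rows, 64), dtype=np.float32)
    for i, seq in enumerate(seqs):
        if len(seq) > GROUP_MAX_LEN[group]:
            raise ValueError(
                f"sequence of length {len(seq)} exceeds group {group} maximum"
            )
        bi = base_index_track(seq)
        valid = bi >= 0
        boh[i, np.nonzero(valid)[0], bi[valid]] = 1.0
        if len(seq) >= 3:
            ci = codon_index_track(seq)
            valid = ci >= 0
            coh[i, np.nonzero(valid)[0], ci[valid]] = 1.0
    return boh, coh
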