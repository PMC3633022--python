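"""Auto- and cross-covariance (ACC) transformation of protein sequences.

A protein of length ``n`` is first encoded as an ``n x 3`` matrix of
z-descriptor values and then collapsed into a fixed-length feature vector of
lagged covariance terms,

    A_jj(l) = sum_{i=1..n-l} Z[j,i] * Z[j,i+l] / (n - l)       (auto)
    C_jk(l) = sum_{i=1..n-l} Z[j,i] * Z[k,i+l] / (n - l)       (cross, j != k)

for lags ``l = 1..L``.  With three descriptors and the default maximum lag
``L = 5`` this yields 9 * 5 = 45 variables, making proteins of any length
directly comparable without alignment.

Feature layout (frozen, identifier ``acc-z3-pairmajor-v1``): descriptor-pair
major, lag minor -- ``A11_l1 .. A11_l5, A22_l1 .. , A33, C12, C13, C21, C23,
C31, C32`` -- so the vector for ``L = 5`` reads ``A11_l1 ... C32_l5``.
Cross terms are directional: ``C12`` pairs z1 at position ``i`` with z2 at
position ``i + l``, while ``C21`` pairs them the other way round, so both are
retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .zscales import STANDARD_AMINO_ACIDS, ZTriple, load_zscale

DEFAULT_LAGS = 5

#: frozen feature-layout identifier written into every serialized model
LAYOUT_ID = "acc-z3-pairmajor-v1"

# (row descriptor j, column descriptor k) in emission order; 0-based indices
_PAIR_ORDER: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2),          # auto terms A11, A22, A33
    (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1),  # cross terms
)
_PAIR_NAMES: tuple[str, ...] = (
    "A11", "A22", "A33", "C12", "C13", "C21", "C23", "C31", "C32",
)


class SequenceError(ValueError):
    """Raised for sequences that cannot be encoded or transformed."""


@dataclass(frozen=True)
class EncodedSequence:
    """A validated protein sequence with its per-residue descriptor matrix."""

    residues: str
    zmatrix: np.ndarray  # n x 3, row i = (z1, z2, z3) of residue i

    @property
    def n(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ACCVector:
    """Fixed-length ACC feature vector of one protein."""

    values: np.ndarray
    layout: str = LAYOUT_ID
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


def feature_names(lags: int = DEFAULT_LAGS) -> list[str]:
    """Column names of the ACC vector in layout order (``A11_l1 .. C32_l5``)."""
    return [f"{pair}_l{l}" for pair in _PAIR_NAMES for l in range(1, lags + 1)]


def _ambiguity_triples(table: Mapping[str, ZTriple]) -> dict[str, ZTriple]:
    """Descriptor triples substituted for ambiguity codes in permissive mode.

    B averages D/N, Z averages E/Q, J averages I/L; X, U and O fall back to
    the column-wise mean of all 20 standard triples.
    """
    def mean(*residues: str) -> ZTriple:
        arr = np.mean([table[r] for r in residues], axis=0)
        return (float(arr[0]), float(arr[1]), float(arr[2]))

    overall = mean(*STANDARD_AMINO_ACIDS)
    return {
        "B": mean("D", "N"),
        "Z": mean("E", "Q"),
        "J": mean("I", "L"),
        "X": overall,
        "U": overall,
        "O": overall,
    }


def encode_sequence(
    seq: str,
    table: Mapping[str, ZTriple] | None = None,
    *,
    permissive: bool = False,
) -> EncodedSequence:
    """Encode an amino-acid string as an ``n x 3`` z-descriptor matrix.

    The input is uppercased and stripped of whitespace/line breaks before
    validation, so sequences pasted in plain format round-trip unchanged.

    Parameters
    ----------
    seq:
        Protein sequence, one-letter codes.
    table:
        Descriptor table; defaults to the built-in Hellberg z-scales.
    permissive:
        If true, ambiguity codes (B, Z, J, X, U, O) are mapped to averaged
        descriptor triples with a warning instead of raising.

    Raises
    ------
    SequenceError
        On an empty sequence, or (in strict mode) on any character outside
        the 20 standard one-letter codes; the message names the offending
        position and character.
    """
    if table is None:
        table = load_zscale()

    cleaned = "".join(seq.split()).upper()
    if not cleaned:
        raise SequenceError("empty protein sequence")

    substitutions = _ambiguity_triples(table) if permissive else {}
    rows: list[ZTriple] = []
    for pos, ch in enumerate(cleaned, start=1):
        if ch in table:
            rows.append(table[ch])
        elif ch in substitutions:
            warnings.warn(
                f"non-standard residue {ch!r} at position {pos} replaced by "
                f"averaged descriptor values",
                stacklevel=2,
            )
            rows.append(substitutions[ch])
        else:
            raise SequenceError(
                f"non-standard residue {ch!r} at position {pos}; expected one "
                f"of the 20 standard one-letter codes"
            )
    return EncodedSequence(residues=cleaned, zmatrix=np.asarray(rows, dtype=float))


def acc_transform(
    enc: EncodedSequence,
    lags: int = DEFAULT_LAGS,
    *,
    source_id: str = "",
) -> ACCVector:
    """Collapse an encoded sequence into its lagged-covariance feature vector.

    For each lag ``l`` the 3 x 3 matrix of lagged products is
    ``Z[:-l].T @ Z[l:] / (n - l)``; its entries are emitted in the frozen
    pair-major layout.  Output length is ``9 * lags`` (45 for the default
    ``lags = 5``).

    Raises
    ------
    SequenceError
        If the sequence is shorter than ``lags + 1`` residues, the minimum
        for every lag to have at least one summand.
    """
    if lags < 1:
        raise ValueError(f"lag count must be >= 1, got {lags}")
    n = enc.n
    if n < lags + 1:
        raise SequenceError(
            f"sequence too short for ACC with L={lags}: length {n}, "
            f"minimum {lags + 1}"
        )

    # Lagged sums can cancel to values many orders below the individual
    # products, so the float64 element-wise products are accumulated and
    # averaged in extended precision before rounding once back to float64.
    Z = enc.zmatrix
    out = np.empty((len(_PAIR_ORDER), lags), dtype=float)
    for l in range(1, lags + 1):
        head, tail = Z[:-l], Z[l:]
        for p, (j, k) in enumerate(_PAIR_ORDER):
            prods = (head[:, j] * tail[:, k]).astype(np.longdouble)
            out[p, l - 1] = float(prods.sum() / (n - l))
    return ACCVector(values=out.ravel(), source_id=source_id)


def write_acc_tsv(
    ids: Sequence[str], X: np.ndarray, path, lags: int = DEFAULT_LAGS
) -> None:
    """Export ACC vectors as a TSV table: id column + named feature columns."""
    import pandas as pd

    df = pd.DataFrame(X, columns=feature_names(lags))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def acc_matrix(
    sequences: Iterable[tuple[str, str]],
    lags: int = DEFAULT_LAGS,
    *,
    table: Mapping[str, ZTriple] | None = None,
    permissive: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Transform ``(id, sequence)`` pairs into an id list and feature matrix."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for seq_id, seq in sequences:
        enc = encode_sequence(seq, table, permissive=permissive)
        rows.append(acc_transform(enc, lags, source_id=seq_id).values)
        ids.append(seq_id)
    return ids, np.asarray(rows, dtype=float)
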