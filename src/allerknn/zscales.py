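"""Hellberg z-scale amino-acid descriptors.

The three z-descriptors summarise the principal physicochemical variation of
the 20 standard amino acids: ``z1`` tracks hydrophobicity, ``z2`` molecular
size and ``z3`` polarity.  The numeric values ship with the package as a
versioned data file (``data/hellberg_z3.tsv``) whose header records the
transcription source.
"""

from __future__ import annotations

from importlib import resources
from types import MappingProxyType
from typing import Mapping, Tuple

import math

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ZTriple = Tuple[float, float, float]

_DATA_FILE = "hellberg_z3.tsv"
_cache: Mapping[str, ZTriple] | None = None


class ZScaleError(RuntimeError):
    """Raised when the built-in descriptor table fails validation."""


def load_zscale() -> Mapping[str, ZTriple]:
    """Return the immutable 20-residue z-scale table.

    The table maps one-letter residue codes to ``(z1, z2, z3)`` triples.
    It is loaded once from the packaged data file and cached; repeated calls
    return the same mapping.

    Raises
    ------
    ZScaleError
        If the packaged table is incomplete or contains non-finite values.
    """
    global _cache
    if _cache is not None:
        return _cache

    text = resources.files("allerknn.data").joinpath(_DATA_FILE).read_text()
    entries: dict[str, ZTriple] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ZScaleError(f"malformed z-scale row: {line!r}")
        residue = parts[0]
        try:
            triple = (float(parts[1]), float(parts[2]), float(parts[3]))
        except ValueError as exc:
            raise ZScaleError(f"non-numeric z-scale row: {line!r}") from exc
        if residue in entries:
            raise ZScaleError(f"duplicate residue {residue!r} in z-scale table")
        if not all(math.isfinite(v) for v in triple):
            raise ZScaleError(f"non-finite z-value for residue {residue!r}")
        entries[residue] = triple

    if set(entries) != set(STANDARD_AMINO_ACIDS):
        missing = sorted(set(STANDARD_AMINO_ACIDS) - set(entries))
        extra = sorted(set(entries) - set(STANDARD_AMINO_ACIDS))
        raise ZScaleError(
            f"z-scale table must cover exactly the 20 standard residues "
            f"(missing {missing}, unexpected {extra})"
        )

    _cache = MappingProxyType(dict(sorted(entries.items())))
    return _cache
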