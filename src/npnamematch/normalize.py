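"""Cleaning and fixed-length integer encoding of product-name strings.

Free-text drug-name strings from spontaneous reporting systems are noisy:
mixed case, punctuation, dosage suffixes, the occasional accented letter.
This module reduces every raw string to the restricted alphabet
``{A-Z, space}`` and encodes it as a fixed-length integer vector suitable
for a character-level neural model:

* letters ``A``-``Z`` map to ``1``-``26``,
* the space character maps to ``27``,
* ``0`` is reserved for right-padding up to :data:`MAX_LEN` (65) positions.

Strings longer than the cutoff are rejected rather than truncated, so the
encoding is lossless on everything it accepts.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyAfterCleaning, InvalidCode, TooLong

#: Fixed encoded-sequence length; names longer than this are rejected.
MAX_LEN = 65
#: Integer code of the space character.
SPACE_CODE = 27
#: Vocabulary size including the padding symbol 0.
VOCAB_SIZE = 28

_WS_RUN = re.compile(r"\s+")


def clean_name(raw: str, *, max_len: int | None = None) -> str:
    """Normalize a raw name string to the alphabet ``{A-Z, space}``.

    Non-alphabetic characters are deleted in place (no replacement
    character is inserted), accented letters are transliterated to their
    closest ASCII letter via Unicode decomposition, the result is
    uppercased, and whitespace runs are collapsed to a single space with
    leading/trailing whitespace stripped.

    Parameters
    ----------
    raw
        Arbitrary unicode string.
    max_len
        If given, raise :class:`TooLong` when the cleaned result exceeds it.

    Raises
    ------
    EmptyAfterCleaning
        If no letter survives cleaning (e.g. ``"123!!"``).
    TooLong
        If ``max_len`` is given and the cleaned name is longer.
    """
    # NFKD decomposition turns e.g. "é" into "e" + combining accent; the
    # combining mark is then dropped by the alphabet filter below.
    decomposed = unicodedata.normalize("NFKD", raw)
    kept: list[str] = []
    for ch in decomposed:
        if ch.isspace():
            kept.append(" ")
        else:
            up = ch.upper()
            if "A" <= up <= "Z":
                kept.append(up)
    cleaned = _WS_RUN.sub(" ", "".join(kept)).strip()
    if not any("A" <= c <= "Z" for c in cleaned):
        raise EmptyAfterCleaning(f"no letters survive cleaning of {raw!r}")
    if max_len is not None and len(cleaned) > max_len:
        raise TooLong(f"cleaned name has {len(cleaned)} characters (max {max_len})")
    return cleaned


def encode_name(name: str, *, max_len: int = MAX_LEN) -> np.ndarray:
    """Encode a clean name as a right-padded integer vector of length ``max_len``.

    ``A``-``Z`` map to ``1``-``26`` and space to ``27``; the remainder of
    the vector is zero padding.

    Raises
    ------
    TooLong
        If the name has more than ``max_len`` characters.
    InvalidCode
        If the name contains a character outside ``{A-Z, space}``.
    """
    if len(name) > max_len:
        raise TooLong(f"{name!r} has {len(name)} characters (max {max_len})")
    seq = np.zeros(max_len, dtype=np.int64)
    for i, ch in enumerate(name):
        if ch == " ":
            seq[i] = SPACE_CODE
        elif "A" <= ch <= "Z":
            seq[i] = ord(ch) - ord("A") + 1
        else:
            raise InvalidCode(f"character {ch!r} is outside the clean alphabet")
    if not seq.any():
        raise InvalidCode("cannot encode an empty name")
    return seq


def decode_sequence(seq: Sequence[int] | np.ndarray) -> str:
    """Invert :func:`encode_name` on the non-padding prefix.

    Raises
    ------
    InvalidCode
        If any entry lies outside ``{0..27}``, a zero precedes a non-zero
        entry, or the sequence is all padding.
    """
    arr = np.asarray(seq, dtype=np.int64)
    if arr.ndim != 1:
        raise InvalidCode("encoded sequence must be one-dimensional")
    if ((arr < 0) | (arr > SPACE_CODE)).any():
        raise InvalidCode("entry outside {0..27}")
    nz = np.nonzero(arr)[0]
    if nz.size == 0:
        raise InvalidCode("all-padding sequence")
    last = nz[-1]
    if (arr[: last + 1] == 0).any():
        raise InvalidCode("padding zero precedes a non-padding entry")
    chars = [" " if v == SPACE_CODE else chr(ord("A") + int(v) - 1) for v in arr[: last + 1]]
    return "".join(chars)


def encode_batch(names: Iterable[str], *, max_len: int = MAX_LEN) -> np.ndarray:
    """Encode many clean names into an ``(n, max_len)`` integer matrix."""
    rows = [encode_name(n, max_len=max_len) for n in names]
    return np.stack(rows) if rows else np.zeros((0, max_len), dtype=np.int64)


def read_names(path: str | Path, *, column: str = "name") -> list[str]:
    """Read raw name strings from a text or CSV/TSV file.

    ``.csv`` / ``.tsv`` files must carry a header with ``column``; any
    other extension is treated as plain text, one name per line (blank
    lines skipped). No cleaning is applied.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".csv", ".tsv"}:
        delim = "\t" if suffix == ".tsv" else ","
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or column not in reader.fieldnames:
                raise ValueError(f"{path} has no {column!r} column")
            return [row[column] for row in reader if row[column]]
    with path.open(encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
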