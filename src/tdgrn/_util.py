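"""Small shared helpers: natural identifier ordering and stable hashing."""

from __future__ import annotations

import re
import zlib

_DIGIT_RUN = re.compile(r"(\d+)")


def natural_key(identifier: str) -> tuple:
    """Sort key comparing embedded integer runs numerically.

    Benchmark-style gene ids sort G1 < G2 < ... < G10 < G100 instead of
    lexicographically.
    """
    parts = _DIGIT_RUN.split(identifier)
    # even indices: text chunks, odd indices: digit runs
    return tuple(
        (1, int(p)) if i % 2 else (0, p) for i, p in enumerate(parts) if p != ""
    )


def natural_sorted(identifiers) -> list[str]:
    return sorted(identifiers, key=natural_key)


def stable_hash(key: tuple) -> int:
    """Deterministic non-negative hash of a key tuple of strings.

    crc32 of a canonical rendering; identical across processes and runs
    (unlike Python's per-run randomized str hash).
    """
    canon = "\x1f".join(str(part) for part in key)
    return zlib.crc32(canon.encode("utf-8"))
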