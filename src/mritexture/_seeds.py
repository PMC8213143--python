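"""Deterministic seed derivation for cohort generation.

Per-subject and per-contrast random streams are derived from a single master
seed with a splitmix64-style integer mix, so that inserting or removing one
subject never perturbs the noise realisations of the others.
"""

from __future__ import annotations

import zlib

_MASK64 = 0xFFFFFFFFFFFFFFFF


def splitmix64(x: int) -> int:
    """One round of the splitmix64 output mix (stable across platforms)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_seed(*parts: int) -> int:
    """Mix an ordered tuple of integers into one 64-bit stream seed."""
    state = 0
    for p in parts:
        state = splitmix64(state ^ (int(p) & _MASK64))
    return state


def label_hash(label: str) -> int:
    """Stable 32-bit hash of a text label (contrast names etc.)."""
    return zlib.crc32(label.encode("utf-8")) & 0xFFFFFFFF
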