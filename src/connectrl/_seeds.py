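"""Deterministic seed derivation.

A splitmix64-style integer mix fans one master seed out into independent
per-subject / per-stage streams. Derived seeds are reproducible regardless
of the order in which they are requested, and are reduced below 2**31 so
they are safe for any RNG API.
"""

from __future__ import annotations

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_seed(master_seed: int, *parts: int) -> int:
    """Mix ``master_seed`` with integer ``parts`` into a seed in [0, 2**31)."""
    state = _splitmix64(master_seed & _MASK64)
    for part in parts:
        state = _splitmix64(state ^ (part & _MASK64))
    return state & 0x7FFFFFFF
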