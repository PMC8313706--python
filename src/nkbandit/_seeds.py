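"""Deterministic seed derivation so every stage fans out from one master seed."""

from __future__ import annotations

import zlib

_MOD = 2**31 - 1


def derive_seed(master: int, *keys) -> int:
    """Hash a master seed and a key path into a 31-bit child seed.

    Pure arithmetic (no salted hashing), so the derivation is stable across
    processes and platforms and can be recorded in a manifest.
    """
    h = int(master) % _MOD
    for key in keys:
        if isinstance(key, (int, bool)):
            v = int(key)
        else:
            v = zlib.crc32(str(key).encode("utf-8"))
        h = (h * 1_000_003 + v + 12_345) % _MOD
    return h
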