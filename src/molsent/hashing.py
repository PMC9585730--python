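"""Platform-stable 32-bit hashing of substructure invariant tuples.

Substructure identifiers are FNV-1a hashes of the little-endian 4-byte
serialization of an integer invariant tuple, truncated to 32 bits.  FNV-1a is
seedless and arithmetic-only, so identifiers are reproducible across machines
and Python versions (unlike the builtin ``hash``).
"""

from __future__ import annotations

import struct
from collections.abc import Iterable

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF


def fnv1a_32(data: bytes) -> int:
    """FNV-1a over ``data``, returned as an unsigned 32-bit integer."""
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK32
    return h


def hash_invariants(fields: Iterable[int]) -> int:
    """Hash an integer tuple to a 32-bit identifier.

    Each field is serialized as a little-endian 4-byte word (two's complement
    for negative values, e.g. formal charges), so the byte stream — and hence
    the identifier — is independent of platform endianness and word size.
    """
    payload = b"".join(struct.pack("<I", f & _MASK32) for f in fields)
    return fnv1a_32(payload)
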