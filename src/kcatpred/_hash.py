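"""Stable non-cryptographic hashing for fingerprint bits.

FNV-1a over UTF-8 bytes, 64-bit. Chosen because it is trivially
re-implementable outside this package (the test suite carries an
independent copy as an oracle) and identical on every platform and
Python version, unlike the process-randomised builtin ``hash``.
"""

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


def fnv1a_64(text: str) -> int:
    """64-bit FNV-1a hash of ``text`` encoded as UTF-8."""
    h = _FNV_OFFSET
    for byte in text.encode("utf-8"):
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK64
    return h


def hash_to_bit(text: str, n_bits: int) -> int:
    """Map a canonical substructure identifier onto a bit index in [0, n_bits)."""
    return fnv1a_64(text) % n_bits
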