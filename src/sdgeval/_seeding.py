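"""Deterministic child-seed derivation.

A single master seed drives the whole pipeline.  Every stage that needs
randomness derives its own child seed from the master seed plus a tuple of
string/int tokens naming the stage (module, dataset, variant, replicate).
Two stages with different token tuples therefore get statistically
independent streams, and re-running with the same master seed reproduces
every stream bit-for-bit.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(master: int, *tokens: object) -> int:
    """Derive a deterministic 31-bit seed from ``master`` and ``tokens``.

    The derivation hashes the decimal master seed together with the
    ``repr`` of each token, so any hashable-by-name coordinate (dataset id,
    generator id, replicate index, ...) can participate.
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for tok in tokens:
        h.update(b"\x1f")
        h.update(repr(tok).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
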