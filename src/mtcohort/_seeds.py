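"""Deterministic per-stage seed derivation from a single master seed."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, label: str) -> int:
    """A reproducible 31-bit seed for a named stage of a pipeline run.

    Hashing the ``(master, label)`` pair keeps stages statistically
    independent while every stage remains recoverable from the master seed.
    """
    digest = hashlib.sha256(f"{int(master)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
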