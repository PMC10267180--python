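"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["stable_seed"]


def stable_seed(*parts: object) -> int:
    """Derive a 32-bit seed from arbitrary parts, stably across runs/platforms.

    Used to give each plant/fold its own stream so that adding a plant to a
    cohort does not reshuffle the randomness of the others.
    """
    key = ":".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
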