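"""Shared helpers: seed fan-out and logging setup."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("enumstack")


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a component seed from a global seed and a label path.

    A single user-facing seed fans out to every stochastic component through
    a SHA-256 hash of ``(seed, *tokens)``, so components stay independent and
    the whole run is reproducible from one integer. The result is always in
    ``[0, 2**31)``.
    """
    h = hashlib.sha256(repr((int(seed),) + tokens).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
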