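"""Deterministic child-seed derivation.

Child seeds are derived by hashing the master seed together with string
context tokens (variant label, model index, trajectory index, ...) so that
runs are reproducible regardless of execution order or parallelism.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *context: object) -> int:
    """Return a stable 63-bit seed derived from ``master_seed`` and context.

    The derivation is sha256 over a canonical string encoding; it is stable
    across processes and platforms (no reliance on ``hash()``).
    """
    token = "\x1f".join([str(int(master_seed))] + [str(c) for c in context])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") & 0x7FFFFFFFFFFFFFFF
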