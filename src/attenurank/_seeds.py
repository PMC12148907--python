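"""Deterministic seed derivation.

Every stage of the pipeline draws randomness from its own child seed,
derived from one master seed plus a stage tag.  This keeps each stage
reproducible in isolation (re-running ``rank`` does not perturb the
synthesizer) while the whole pipeline is a function of a single integer.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(master: int, *tags: object) -> int:
    """Derive a stable 31-bit child seed from a master seed and tags.

    The derivation is a SHA-256 hash of the master seed and the tag
    sequence, truncated to ``[0, 2**31)``.  It is stable across platforms
    and Python processes (unlike ``hash()``).
    """
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
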