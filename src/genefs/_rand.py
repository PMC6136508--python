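"""Deterministic seed derivation.

Every stochastic stage in the package derives its own seed from a single
top-level seed plus a short string tag.  The rule is a truncated BLAKE2b
hash of ``"{seed}:{tag1}:{tag2}:..."``, reduced modulo 2**31, so a run log
that records the top-level seed suffices to reproduce any stage.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(seed: int, *tags: object) -> int:
    """Derive a stage seed from a top-level seed and a tag sequence.

    The same ``(seed, tags)`` always yields the same child, and distinct
    tags yield (with overwhelming probability) distinct children.  The
    result is in ``[0, 2**31)`` so it is valid for every RNG consumer.
    """
    key = ":".join([str(int(seed))] + [str(t) for t in tags])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
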