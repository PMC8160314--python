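"""Deterministic stage-seed derivation.

Every pipeline stage draws its seed from the global seed and its own
name, so adding or reordering stages never perturbs the randomness of
the others, and the whole run is reproducible from one integer.
"""

from __future__ import annotations

import hashlib


def derive_seed(global_seed: int | None, *tags: str) -> int | None:
    """Stable 31-bit seed from a global seed and a tag path."""
    if global_seed is None:
        return None
    token = "|".join([str(int(global_seed)), *map(str, tags)])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
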