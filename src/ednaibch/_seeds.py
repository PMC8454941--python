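"""Stable derivation of per-stage / per-task RNG seeds from one global seed.

Hashing the label together with the global seed keeps every stage
individually reproducible: re-running a single stage with the global seed
gives the same stream it saw inside a full run.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *labels) -> int:
    """A deterministic 31-bit seed from a global seed and string labels."""
    key = ":".join([str(int(seed))] + [str(l) for l in labels])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
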