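"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2^31) from one global seed.

    Hashing the stage name together with the global seed lets stages be
    re-run in isolation with the same randomness they saw in a full run.
    """
    digest = hashlib.sha256(f"{stage}:{int(global_seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
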