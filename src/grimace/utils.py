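"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["stable_seed"]


def stable_seed(global_seed: int, *tokens) -> int:
    """Deterministic sub-seed from a global seed plus string tokens.

    blake2b-based so the fan-out is reproducible across processes and
    platforms (unlike builtin ``hash``); results are < 2**31 so they are
    valid seeds everywhere.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(global_seed)).encode())
    for t in tokens:
        h.update(b"/")
        h.update(str(t).encode())
    return int.from_bytes(h.digest(), "little") % (2 ** 31)
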