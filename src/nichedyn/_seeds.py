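"""Named, reproducible seed derivation from one root seed."""

from __future__ import annotations

import zlib


def derive_seed(root: int, name: str) -> int:
    """Stable child seed for a named random substream, below 2**31."""
    return (int(root) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)
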