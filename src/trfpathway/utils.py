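"""Seed plumbing shared across modules.

One user-facing seed expands deterministically into every per-replicate,
per-permutation and per-forest seed via :class:`numpy.random.SeedSequence`;
no module touches global RNG state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(*keys: int) -> int:
    """Deterministically derive a child seed (< 2**31) from integer keys."""
    state = np.random.SeedSequence([int(k) for k in keys]).generate_state(1, np.uint32)
    return int(state[0] & 0x7FFFFFFF)
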