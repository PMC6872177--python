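"""Small shared utilities."""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seeds"]


def spawn_seeds(base: int, n: int) -> list[int]:
    """``n`` statistically independent child seeds derived from ``base``.

    Uses :class:`numpy.random.SeedSequence` spawning, so replicate streams
    are decorrelated regardless of the base value; results fit in int32.
    """
    ss = np.random.SeedSequence(base)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]
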