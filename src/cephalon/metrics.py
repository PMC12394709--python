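"""Recovery metrics for synthetic-ground-truth experiments."""

from __future__ import annotations

import numpy as np

__all__ = ["dice"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two boolean masks.

    Returns 1.0 when both masks are empty (perfect agreement on nothing).
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    return 2.0 * int(np.logical_and(a, b).sum()) / denom if denom else 1.0
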