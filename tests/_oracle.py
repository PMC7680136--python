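"""Independent brute-force oracle for palindrome detection.

For every candidate midpoint this enumerates the even-length windows centered
there and tests each directly against the span invariants (no N, core
mismatch budget, total arm mismatch budget within the window, complementary
outermost pair unless the window is the bare core), returning the maximal
valid window. It shares no code with the package's seed-extend-trim
detector.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_force_spans(bases: str, core_len=8, max_core_mm=0, max_arm_mm=4):
    """All per-center maximal valid spans as a sorted list of
    (start, end, arm_mm, core_mm)."""
    n = len(bases)
    h = core_len // 2
    arr = np.frombuffer(bases.encode(), dtype="S1")
    comp = np.frombuffer(
        "".join(_COMP.get(b, "X") for b in bases).encode(), dtype="S1"
    )
    out = []
    for c in range(h, n - h + 1):
        L = min(c, n - c)
        left = comp[c - 1 :: -1][:L]  # complement of left arm, inward-out
        right = arr[c : c + L]
        is_n = (arr[c - 1 :: -1][:L] == b"N") | (right == b"N")
        pair_ok = (left == right) & ~is_n
        # windows must stop before the first N on either side
        n_idx = np.flatnonzero(is_n)
        max_k = int(n_idx[0]) if n_idx.size else L
        if max_k < h:
            continue
        mm = np.cumsum(~pair_ok)
        core_mm = int(mm[h - 1])
        if core_mm > max_core_mm:
            continue
        best = None
        for k in range(h, max_k + 1):
            arm_mm = int(mm[k - 1]) - core_mm
            if arm_mm > max_arm_mm:
                break  # mismatch count only grows with k
            if k > h and not pair_ok[k - 1]:
                continue  # outermost pair must be complementary
            best = (c - k, c + k, arm_mm, core_mm)
        if best is not None:
            out.append(best)
    out.sort()
    return out
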