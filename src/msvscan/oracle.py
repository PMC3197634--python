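"""Exhaustive path enumeration over the multihit local alignment model.

Ground-truth oracle for the DP implementations on tiny instances: every
state path through the model (N/B flanks, one or more core segments joined
through E -> J -> B, C tail) is enumerated explicitly and scored in bits,
with the null model's transition score subtracted exactly as the DPs do.

Two views share the machinery:

* ``view="msv"`` — ungapped segments, uniform entry 2/(M(M+1)), match-match
  transitions free (probability 1.0);
* ``view="gapped"`` — full core model with match/insert/delete transitions
  and the 2(M-k+1)/(M(M+1)) entry distribution.

Only match states may end a segment (exit to E), matching the DPs.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AMINO
from .profile import SearchProfile

MAX_CELLS = 64  # guard: refuse instances with M * L beyond this


def enumerate_path_scores(
    sp: SearchProfile, seq: str, view: str = "gapped",
    max_segments: int | None = None,
) -> list[float]:
    """Bit scores of every complete state path for ``seq`` under the model."""
    if view not in ("msv", "gapped"):
        raise ValueError("view must be 'msv' or 'gapped'")
    x = AMINO.encode(seq)
    L = len(x)
    if L != sp.L:
        sp = sp.with_length(L)
    M = sp.M
    if M * L > MAX_CELLS:
        raise ValueError(f"instance too large to enumerate (M*L > {MAX_CELLS})")

    s = sp.scores  # (M, 21)
    loop_b, move_b = sp.loop_bits, sp.move_bits
    tee = -1.0
    if view == "msv":
        entry_b = np.full(M, sp.entry_msv_bits())
        tb = None
    else:
        entry_b = sp.entry_vit_bits()
        tb = sp.core_transition_bits()
    null_b = sp.null.transition_bits()

    out: list[float] = []

    def from_match(k: int, i: int, sc: float, nseg: int) -> None:
        # exit to E (probability 1 in the implicit local model)
        at_e(i, sc, nseg)
        if view == "msv":
            if k + 1 < M and i < L:
                from_match(k + 1, i + 1, sc + s[k + 1, x[i]], nseg)
            return
        if i < L and k + 1 < M:
            from_match(k + 1, i + 1, sc + tb["mm"][k] + s[k + 1, x[i]], nseg)
        if i < L:
            from_insert(k, i + 1, sc + tb["mi"][k], nseg)
        if k + 1 < M:
            from_delete(k + 1, i, sc + tb["md"][k], nseg)

    def from_insert(k: int, i: int, sc: float, nseg: int) -> None:
        if i < L and k + 1 < M:
            from_match(k + 1, i + 1, sc + tb["im"][k] + s[k + 1, x[i]], nseg)
        if i < L:
            from_insert(k, i + 1, sc + tb["ii"][k], nseg)

    def from_delete(k: int, i: int, sc: float, nseg: int) -> None:
        if i < L and k + 1 < M:
            from_match(k + 1, i + 1, sc + tb["dm"][k] + s[k + 1, x[i]], nseg)
        if k + 1 < M:
            from_delete(k + 1, i, sc + tb["dd"][k], nseg)

    def at_b(i: int, sc: float, nseg: int) -> None:
        if max_segments is not None and nseg >= max_segments:
            return
        if i >= L:
            return
        for k in range(M):
            from_match(k, i + 1, sc + entry_b[k] + s[k, x[i]], nseg + 1)

    def at_e(i: int, sc: float, nseg: int) -> None:
        # E -> J -> (loops) -> B for another segment
        for j in range(i, L):
            at_b(j, sc + tee + (j - i) * loop_b + move_b, nseg)
        # E -> C -> (loops) -> T
        out.append(sc + tee + (L - i) * loop_b + move_b - null_b)

    # S -> N (loops) -> B
    for i in range(0, L):
        at_b(i, i * loop_b + move_b, 0)

    return out


def brute_force_msv(sp: SearchProfile, seq: str,
                    max_segments: int | None = None) -> float:
    """Exact optimal multihit ungapped score by enumeration (tiny instances)."""
    return max(enumerate_path_scores(sp, seq, "msv", max_segments))


def brute_force_viterbi(sp: SearchProfile, seq: str) -> float:
    return max(enumerate_path_scores(sp, seq, "gapped"))


def brute_force_forward(sp: SearchProfile, seq: str) -> float:
    """Exact log2 sum over all gapped paths."""
    scores = np.array(enumerate_path_scores(sp, seq, "gapped"))
    m = scores.max()
    return float(m + np.log2(np.sum(np.exp2(scores - m))))
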