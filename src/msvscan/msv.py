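"""Multiple Segment Viterbi (MSV) scoring: the multihit ungapped filter.

The MSV model keeps only the match states of the profile (match-match
transitions treated as probability 1.0, so extension of an ungapped diagonal
is free), the uniform entry 2/(M(M+1)), and the flanking/multihit states
N, B, E, J, C.  Its optimal score is a log-odds Viterbi score against the
geometric i.i.d. null model.

Three implementations share this model:

* :func:`msv_score` — full floating-point serial DP, O(M) memory.
* :func:`msv_filter_scalar` — saturated unsigned-byte DP in plain (unstriped)
  cell order; the layout oracle for the striped filter.
* :func:`msv_filter` — the striped saturated-byte filter (emulated V-wide
  vectors), bit-identical to the scalar byte DP.

In the byte filters the N/C/J self-loop transitions are scored as zero cost
during the recursion; their missing total contribution, L*log2(L/(L+3)),
which tends to -3/ln2 ~ -4.3 bits for large L, is added back as a constant
at termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO
from .profile import SearchProfile
from .striped import ReducedProfile, shift_slots, unstripe

#: large-L limit of the total N/C/J self-loop contribution, in bits (-4.33)
NCJ_CONSTANT_BITS = -3.0 / np.log(2.0)


def ncj_loop_total_bits(L: int) -> float:
    """Total cost L*log2(L/(L+3)) of scoring ~L N/C/J self-loops exactly."""
    return L * np.log2(L / (L + 3.0))


@dataclass
class MsvResult:
    score: float
    overflowed: bool = False
    raw_max: int | None = None


def _check(rp: ReducedProfile, sp: SearchProfile) -> None:
    if rp.M != sp.M:
        raise ValueError("reduced profile does not match search profile (M differs)")


# ---------------------------------------------------------------------------
# full-precision serial DP
# ---------------------------------------------------------------------------

def msv_score(sp: SearchProfile, seq: str) -> float:
    """Optimal multihit ungapped log-odds score in bits, full precision."""
    enc = AMINO.encode(seq)
    return float(msv_score_batch(sp, enc[None, :])[0])


def msv_score_batch(sp: SearchProfile, X: np.ndarray) -> np.ndarray:
    """Vectorized :func:`msv_score` over an (n, L) encoded sequence batch."""
    n, L = X.shape
    if L != sp.L:
        sp = sp.with_length(L)
    s = sp.scores.T          # (21, M)
    loop_b, move_b = sp.loop_bits, sp.move_bits
    tbm = sp.entry_msv_bits()
    tee = -1.0               # t(E->J) = t(E->C) = 0.5

    NEG = -np.inf
    mrow = np.full((n, sp.M), NEG)
    N = np.zeros(n)
    B = np.full(n, move_b)
    J = np.full(n, NEG)
    C = np.full(n, NEG)
    diag = np.empty_like(mrow)
    for i in range(L):
        diag[:, 0] = NEG
        diag[:, 1:] = mrow[:, :-1]
        mrow = s[X[:, i]] + np.maximum(diag, (B + tbm)[:, None])
        E = mrow.max(axis=1)
        J = np.maximum(J + loop_b, E + tee)
        C = np.maximum(C + loop_b, E + tee)
        N = N + loop_b
        B = np.maximum(N, J) + move_b
    return C + move_b - sp.null.transition_bits()


# ---------------------------------------------------------------------------
# saturated byte arithmetic (emulated)
# ---------------------------------------------------------------------------

def _sat_step(sv: np.ndarray, bias: int, cost: np.ndarray) -> np.ndarray:
    """Saturated  sv (+) bias (-) cost  on int arrays emulating uint8."""
    return np.maximum(np.minimum(sv + bias, 255) - cost, 0)


def _byte_constants(rp: ReducedProfile, sp: SearchProfile) -> tuple[int, int]:
    """L-dependent (tjb, tjbm) byte costs for the configured target length."""
    tjb = int(min(255, round(-rp.msv_scale * sp.move_bits)))
    return tjb, min(255, tjb + rp.tbm_cost)


def _filter_bits(rp: ReducedProfile, sp: SearchProfile, raw: np.ndarray) -> np.ndarray:
    """Unwind raw byte maxima to bit scores.

    raw holds base + scale*(score without N/C/J loop costs); the constant
    -4.3-bit term re-adds the loop contribution and the null model's
    transition score is subtracted exactly, as in the full-precision DP.
    """
    return ((raw - rp.msv_base) / rp.msv_scale
            + NCJ_CONSTANT_BITS - sp.null.transition_bits())


def msv_filter_scalar(rp: ReducedProfile, sp: SearchProfile, seq: str) -> MsvResult:
    """Unstriped saturated-byte MSV DP (reference for layout equivalence)."""
    _check(rp, sp)
    enc = AMINO.encode(seq)
    if len(enc) != sp.L:
        sp = sp.with_length(len(enc))
    cost = unstripe(rp.msv_cost.astype(int), rp.M)  # (21, M)
    bias, base, tec = rp.msv_bias, rp.msv_base, rp.tec_cost
    tjb, tjbm = _byte_constants(rp, sp)

    dp = np.zeros(rp.M, dtype=int)
    xJ = 0
    xB = max(0, base - tjbm)
    overflowed = False
    for x in enc:
        diag = np.empty_like(dp)
        diag[0] = 0
        diag[1:] = dp[:-1]
        dp = _sat_step(np.maximum(diag, xB), bias, cost[x])
        xE = int(dp.max())
        if xE >= 255 - bias:
            overflowed = True
        xJ = max(xJ, max(0, xE - tec))
        xB = max(0, max(base, xJ) - tjbm)
    raw = max(0, xJ - tjb)
    return MsvResult(float(_filter_bits(rp, sp, np.array(raw))),
                     overflowed, raw)


def msv_filter(rp: ReducedProfile, sp: SearchProfile, seq: str) -> MsvResult:
    """Striped saturated-byte MSV filter for one sequence."""
    enc = AMINO.encode(seq)
    scores, over, raw = msv_filter_batch(rp, sp, enc[None, :])
    return MsvResult(float(scores[0]), bool(over[0]), int(raw[0]))


def msv_filter_batch(
    rp: ReducedProfile, sp: SearchProfile, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Striped byte filter over an (n, L) encoded batch.

    Returns (bit scores, overflowed flags, raw byte maxima).  All sequences
    in the batch advance through the same striped recursion; per-sequence
    state is carried in the leading axis.
    """
    _check(rp, sp)
    n, L = X.shape
    if L != sp.L:
        sp = sp.with_length(L)
    Q, V = rp.Q8, rp.V
    cost = rp.msv_cost.astype(np.int16)  # (21, Q, V)
    bias, base, tec = rp.msv_bias, rp.msv_base, rp.tec_cost
    tjb, tjbm = _byte_constants(rp, sp)

    dp = np.zeros((n, Q, V), dtype=np.int16)
    new = np.empty_like(dp)
    xJ = np.zeros(n, dtype=np.int16)
    xB = np.full(n, max(0, base - tjbm), dtype=np.int16)
    overflowed = np.zeros(n, dtype=bool)

    for i in range(L):
        c = cost[X[:, i]]                      # (n, Q, V)
        mpv = shift_slots(dp[:, Q - 1, :], 0)  # wrap of last vector
        xBv = xB[:, None]
        for q in range(Q):
            sv = _sat_step(np.maximum(mpv, xBv), bias, c[:, q, :])
            mpv = dp[:, q, :]
            new[:, q, :] = sv
        dp, new = new, dp
        xE = dp.max(axis=(1, 2))
        overflowed |= xE >= 255 - bias
        np.maximum(xJ, np.maximum(xE - tec, 0), out=xJ)
        xB = np.maximum(np.maximum(base, xJ) - tjbm, 0).astype(np.int16)

    raw = np.maximum(xJ.astype(int) - tjb, 0)
    return _filter_bits(rp, sp, raw), overflowed, raw
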