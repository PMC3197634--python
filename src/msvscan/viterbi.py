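"""Optimal gapped local alignment (Viterbi) scoring.

:func:`viterbi_score` is the full-precision multihit local Viterbi DP over
the complete profile (match/insert/delete transitions, length-dependent
entry distribution, N/C/J flanking states), O(M) memory.

:func:`viterbi_filter` is its reduced-precision form: striped, saturated
signed 16-bit arithmetic in units of 1/500 bits with an integer offset of
12,000 (representable bit scores -89.5 .. 41.5).  The striped layout breaks
the within-row delete chain D(k-1) -> D(k), so delete propagation uses
Farrar's lazy-F scheme: a pessimistic first pass carries delete candidates
vector to vector, then a fixed-point loop propagates chains across the
slot-wrap until nothing changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO
from .profile import SearchProfile
from .striped import (
    ReducedProfile, VIT_MAX_BITS, VIT_OFFSET, VIT_SCALE, WORD_MAX, WORD_MIN,
    shift_slots, words,
)

_VERY_NEG = -1.0e30  # finite stand-in for -inf in cumulative-sum tricks


@dataclass
class ViterbiResult:
    score: float
    overflowed: bool = False


def viterbi_filter_max_bits() -> float:
    """Maximum representable Viterbi-filter bit score (41.5 to one decimal)."""
    return VIT_MAX_BITS


# ---------------------------------------------------------------------------
# full-precision DP
# ---------------------------------------------------------------------------

def viterbi_score(sp: SearchProfile, seq: str) -> float:
    """Optimal multihit gapped local alignment log-odds score, in bits."""
    enc = AMINO.encode(seq)
    return float(viterbi_score_batch(sp, enc[None, :])[0])


def viterbi_score_batch(sp: SearchProfile, X: np.ndarray) -> np.ndarray:
    n, L = X.shape
    if L != sp.L:
        sp = sp.with_length(L)
    M = sp.M
    s = sp.scores.T  # (21, M)
    tb = {k: np.maximum(v, _VERY_NEG) for k, v in sp.core_transition_bits().items()}
    entry = sp.entry_vit_bits()
    loop_b, move_b = sp.loop_bits, sp.move_bits

    def shifted(a):  # source value at k-1, aligned with target k
        out = np.full_like(a, _VERY_NEG)
        out[1:] = a[:-1]
        return out

    tmm_s, tim_s, tdm_s = shifted(tb["mm"]), shifted(tb["im"]), shifted(tb["dm"])
    # cumulative delete-extension cost for the within-row delete scan
    cd = np.concatenate([[0.0], np.cumsum(tb["dd"])])  # cd[j] = sum dd[:j]

    mrow = np.full((n, M), _VERY_NEG)
    irow = np.full((n, M), _VERY_NEG)
    drow = np.full((n, M), _VERY_NEG)
    N = np.zeros(n)
    B = np.full(n, move_b)
    J = np.full(n, _VERY_NEG)
    C = np.full(n, _VERY_NEG)

    for i in range(L):
        diag = lambda a: np.concatenate(
            [np.full((n, 1), _VERY_NEG), a[:, :-1]], axis=1)
        mnew = s[X[:, i]] + np.maximum.reduce([
            B[:, None] + entry,
            diag(mrow) + tmm_s,
            diag(irow) + tim_s,
            diag(drow) + tdm_s,
        ])
        inew = np.maximum(mrow + tb["mi"], irow + tb["ii"])
        # delete scan: D(k) = max_{j<k} M(j) + md(j) + sum(dd[j+1..k-1])
        u = mnew + tb["md"] - cd[1:]
        run = np.maximum.accumulate(u, axis=1)
        dnew = np.full_like(mnew, _VERY_NEG)
        dnew[:, 1:] = cd[1:-1] + run[:, :-1]
        mrow, irow, drow = mnew, inew, dnew
        E = mrow.max(axis=1)
        J = np.maximum(J + loop_b, E - 1.0)
        C = np.maximum(C + loop_b, E - 1.0)
        N = N + loop_b
        B = np.maximum(N, J) + move_b
    return C + move_b - sp.null.transition_bits()


# ---------------------------------------------------------------------------
# striped saturated-word filter
# ---------------------------------------------------------------------------

def _sat(a: np.ndarray) -> np.ndarray:
    return np.clip(a, WORD_MIN, WORD_MAX)


def viterbi_filter(rp: ReducedProfile, sp: SearchProfile, seq: str) -> ViterbiResult:
    enc = AMINO.encode(seq)
    sc, over = viterbi_filter_batch(rp, sp, enc[None, :])
    return ViterbiResult(float(sc[0]), bool(over[0]))


def viterbi_filter_batch(
    rp: ReducedProfile, sp: SearchProfile, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Striped 16-bit Viterbi filter over an (n, L) encoded batch."""
    if rp.M != sp.M:
        raise ValueError("reduced profile does not match search profile (M differs)")
    n, L = X.shape
    if L != sp.L:
        sp = sp.with_length(L)
    Q, V = rp.Qw, rp.Vw
    emis = rp.vit_emis.astype(np.int32)  # (21, Q, V)
    t_bm = rp.t_bm.astype(np.int32)
    t_mm, t_im, t_dm = (rp.t_mm.astype(np.int32), rp.t_im.astype(np.int32),
                        rp.t_dm.astype(np.int32))
    t_mi, t_ii = rp.t_mi.astype(np.int32), rp.t_ii.astype(np.int32)
    t_md, t_dd = rp.t_md.astype(np.int32), rp.t_dd.astype(np.int32)

    move_w = int(words(sp.move_bits))
    tee_w = int(words(-1.0))  # E->J and E->C, probability one-half
    # error-diffused loop cost: per-row integer increments whose cumulative
    # sum tracks 500 * i * loop_bits within half a unit at every row, so the
    # tiny N/C/J self-loop cost cannot accumulate rounding error over L rows
    cum = np.round(VIT_SCALE * sp.loop_bits * np.arange(L + 1)).astype(np.int32)
    loop_inc = np.diff(cum)

    mx = np.full((n, Q, V), WORD_MIN, dtype=np.int32)
    ix = np.full_like(mx, WORD_MIN)
    dx = np.full_like(mx, WORD_MIN)
    m_new = np.empty_like(mx)
    i_new = np.empty_like(mx)
    d_new = np.empty_like(mx)

    xN = np.full(n, VIT_OFFSET, dtype=np.int32)
    xB = np.full(n, VIT_OFFSET + move_w, dtype=np.int32)
    xJ = np.full(n, WORD_MIN, dtype=np.int32)
    xC = np.full(n, WORD_MIN, dtype=np.int32)
    overflowed = np.zeros(n, dtype=bool)

    for i in range(L):
        e = emis[X[:, i]]  # (n, Q, V)
        mpv = shift_slots(mx[:, Q - 1, :], WORD_MIN)
        ipv = shift_slots(ix[:, Q - 1, :], WORD_MIN)
        dpv = shift_slots(dx[:, Q - 1, :], WORD_MIN)
        dcv = np.full((n, V), WORD_MIN, dtype=np.int32)
        xEv = np.full((n, V), WORD_MIN, dtype=np.int32)
        xBv = xB[:, None]
        for q in range(Q):
            sv = np.maximum.reduce([
                _sat(xBv + t_bm[q]),
                _sat(mpv + t_mm[q]),
                _sat(ipv + t_im[q]),
                _sat(dpv + t_dm[q]),
            ])
            sv = _sat(sv + e[:, q, :])
            np.maximum(xEv, sv, out=xEv)
            mpv, ipv, dpv = mx[:, q, :], ix[:, q, :], dx[:, q, :]
            m_new[:, q, :] = sv
            d_new[:, q, :] = dcv
            dcv = np.maximum(_sat(sv + t_md[q]), _sat(dcv + t_dd[q]))
            i_new[:, q, :] = np.maximum(_sat(mpv + t_mi[q]), _sat(ipv + t_ii[q]))
        # lazy-F: push delete chains across the slot wrap until fixed point
        for _ in range(V):
            dcv = shift_slots(dcv, WORD_MIN)
            changed = False
            for q in range(Q):
                nd = np.maximum(d_new[:, q, :], dcv)
                if np.any(nd > d_new[:, q, :]):
                    changed = True
                    d_new[:, q, :] = nd
                dcv = _sat(nd + t_dd[q])
            if not changed:
                break
        mx, m_new = m_new, mx
        ix, i_new = i_new, ix
        dx, d_new = d_new, dx

        xE = xEv.max(axis=1)
        overflowed |= xE >= WORD_MAX
        lw = int(loop_inc[i])
        xJ = _sat(np.maximum(xJ + lw, xE + tee_w))
        xC = _sat(np.maximum(xC + lw, xE + tee_w))
        xN = _sat(xN + lw)
        xB = _sat(np.maximum(xN, xJ) + move_w)

    final = _sat(xC + move_w)
    overflowed |= final >= WORD_MAX
    scores = (final - VIT_OFFSET) / VIT_SCALE - sp.null.transition_bits()
    return scores, overflowed
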