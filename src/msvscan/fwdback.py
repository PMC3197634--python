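"""Forward/Backward ensemble scoring.

Two routes to the same quantity (the log2 of the summed odds ratio over the
whole multihit local alignment ensemble):

* a *generic* log-domain implementation using an exact log-sum operation
  (optionally a finite lookup table, :class:`LogSumTable`, for the classic
  table-driven form), kept simple and serial — the reference;
* the *parser*: an odds-ratio-domain implementation with sparse rescaling.
  Values are stored as odds ratios (match emissions enter as e_k(a)/f_a), so
  they are pre-scaled; whenever the E-state value on a row exceeds a trigger
  threshold the whole row is divided by the E value itself and the scale is
  recorded.  Only a single row of match/insert/delete values is stored, plus
  the complete columns of the special states E, N, J, B, C — enough for
  posterior decoding of alignment segment endpoints (B and E usage).

Sparse rescaling is sound for multihit local models: a path whose rescaled
delete chain underflows is always dominated by the alternative path that
re-enters through E -> J -> B, which stays on-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO
from .profile import SearchProfile

#: odds-ratio value of the E cell that triggers a row rescale
RESCALE_TRIGGER = 1.0e10

NEG = -np.inf


# ---------------------------------------------------------------------------
# log-sum
# ---------------------------------------------------------------------------

@dataclass
class LogSumTable:
    """Lookup-table log-sum: max(a,b) + table[|a-b|], in bits.

    With the default 16,000 entries at 1/1000-bit resolution the table spans
    differences up to 16 bits; beyond that the correction term
    log2(1 + 2^-d) < 2.3e-5 bits is dropped.  Worst-case error is below half
    the table resolution.
    """

    resolution: float = 0.001
    n_entries: int = 16000

    def __post_init__(self) -> None:
        d = np.arange(self.n_entries) * self.resolution
        self.entries = np.log2(1.0 + np.exp2(-d))
        self.cutoff = self.n_entries * self.resolution

    def logsum(self, a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        hi = np.maximum(a, b)
        lo = np.minimum(a, b)
        with np.errstate(invalid="ignore"):
            d = hi - lo  # nan when both infinite; masked below
        small = np.isfinite(lo) & (d < self.cutoff)
        d_safe = np.where(small, d, 0.0)
        idx = (d_safe / self.resolution + 0.5).astype(int)
        out = hi + np.where(small, self.entries[idx], 0.0)
        if out.ndim == 0:
            return float(out)
        return out


def logsum(a, b, table: LogSumTable | None = None):
    """log2(2^a + 2^b), exact or via a lookup table."""
    if table is not None:
        return table.logsum(a, b)
    return np.logaddexp2(a, b)


# ---------------------------------------------------------------------------
# generic log-domain Forward (reference)
# ---------------------------------------------------------------------------

def forward_generic(sp: SearchProfile, seq: str,
                    table: LogSumTable | None = None) -> float:
    """Serial log-domain Forward; exact log-sum unless a table is given."""
    x = AMINO.encode(seq)
    L = len(x)
    if L != sp.L:
        sp = sp.with_length(L)
    M = sp.M
    s = sp.scores  # (M, 21)
    tb = sp.core_transition_bits()
    entry = sp.entry_vit_bits()
    loop_b, move_b = sp.loop_bits, sp.move_bits
    ls = (lambda a, b: logsum(a, b, table)) if table is not None else np.logaddexp2

    def shifted(a):
        out = np.full_like(a, NEG)
        out[1:] = a[:-1]
        return out

    tmm_s, tim_s, tdm_s = shifted(tb["mm"]), shifted(tb["im"]), shifted(tb["dm"])

    mrow = np.full(M, NEG)
    irow = np.full(M, NEG)
    drow = np.full(M, NEG)
    N, B, J, C = 0.0, move_b, NEG, NEG
    for i in range(L):
        diag = lambda a: np.concatenate([[NEG], a[:-1]])
        mnew = s[:, x[i]] + ls(ls(B + entry, diag(mrow) + tmm_s),
                               ls(diag(irow) + tim_s, diag(drow) + tdm_s))
        inew = ls(mrow + tb["mi"], irow + tb["ii"])
        dnew = np.full(M, NEG)
        for k in range(1, M):
            dnew[k] = ls(mnew[k - 1] + tb["md"][k - 1],
                         dnew[k - 1] + tb["dd"][k - 1])
        mrow, irow, drow = mnew, inew, dnew
        E = mnew[0]
        for k in range(1, M):
            E = ls(E, mnew[k])
        J = ls(J + loop_b, E - 1.0)
        C = ls(C + loop_b, E - 1.0)
        N = N + loop_b
        B = ls(N, J) + move_b
    return float(C + move_b - sp.null.transition_bits())


# ---------------------------------------------------------------------------
# sparse-rescaled parsers
# ---------------------------------------------------------------------------

@dataclass
class ParserState:
    """Special-state columns and scale bookkeeping from one parser sweep.

    ``specials[name]`` has shape (n, L+1), holding the *stored* (scaled)
    odds-ratio values; ``log2_scale`` records per-row scale factors (zero on
    non-rescaled rows).  For a forward sweep the true value on row i is the
    stored value times 2**cumsum(log2_scale)[i]; for a backward sweep, times
    2**(reverse cumsum from row i to the end).
    """

    kind: str                       # "fwd" | "bwd"
    L: int
    specials: dict[str, np.ndarray]
    log2_scale: np.ndarray          # (n, L+1)
    total_log2_odds: np.ndarray     # (n,), null transitions not included

    @property
    def n(self) -> int:
        return self.log2_scale.shape[0]

    def cumulative_log2(self) -> np.ndarray:
        if self.kind == "fwd":
            return np.cumsum(self.log2_scale, axis=1)
        return np.cumsum(self.log2_scale[:, ::-1], axis=1)[:, ::-1]


class _ScanBlocks:
    """Blocked evaluation of d[k] = d[k-1] * g[k] + h[k] along axis 1.

    The naive closed form cumprod(g) underflows for long high-probability
    delete chains; blocks are cut wherever the cumulative product would fall
    below exp(-400), keeping every intermediate on-scale.
    """

    def __init__(self, g: np.ndarray):
        self.g = g
        K = len(g)
        self.blocks = []
        start, acc = 0, 0.0
        for k in range(1, K):
            if g[k] == 0.0 or acc + np.log(g[k]) < -400.0:
                self.blocks.append((start, k))
                start, acc = k, 0.0
            else:
                acc += np.log(g[k])
        self.blocks.append((start, K))
        # within-block cumulative products over g[s+1 .. e-1] (no zeros there)
        self.W = [np.cumprod(g[s + 1:e]) for s, e in self.blocks]

    def scan(self, h: np.ndarray) -> np.ndarray:
        out = np.empty_like(h)
        carry = np.zeros(h.shape[0])
        for (s, e), W in zip(self.blocks, self.W):
            d0 = carry * self.g[s] + h[:, s]
            out[:, s] = d0
            if e > s + 1:
                cs = np.cumsum(h[:, s + 1:e] / W, axis=1)
                out[:, s + 1:e] = W * (d0[:, None] + cs)
            carry = out[:, e - 1]
        return out


def _probs(sp: SearchProfile):
    c = sp.core
    return dict(mm=c.t_mm, mi=c.t_mi, md=c.t_md, im=c.t_im, ii=c.t_ii,
                dm=c.t_dm, dd=c.t_dd)


def forward_parser_batch(sp: SearchProfile, X: np.ndarray
                         ) -> tuple[np.ndarray, ParserState]:
    """Sparse-rescaled Forward over an (n, L) encoded batch.

    Returns bit scores (null transitions subtracted) and the parser state.
    """
    n, L = X.shape
    if L != sp.L:
        sp = sp.with_length(L)
    M = sp.M
    ods = np.exp2(sp.scores).T          # (21, M) emission odds ratios
    p = _probs(sp)
    entry = sp.entry_vit
    loop, move = sp.loop, sp.move

    def shifted(a):
        out = np.zeros_like(a)
        out[1:] = a[:-1]
        return out

    pmm_s, pim_s, pdm_s = shifted(p["mm"]), shifted(p["im"]), shifted(p["dm"])
    entry_b = entry
    dscan = _ScanBlocks(shifted(p["dd"]))   # g[k] = dd[k-1]
    pmd_sh = shifted(p["md"])               # h[k] = mnew[k-1] * md[k-1]

    m = np.zeros((n, M))
    ins = np.zeros((n, M))
    d = np.zeros((n, M))
    xN = np.ones(n)
    xB = np.full(n, move)
    xJ = np.zeros(n)
    xC = np.zeros(n)
    xE = np.zeros(n)

    spec = {nm: np.zeros((n, L + 1)) for nm in "ENJBC"}
    spec["N"][:, 0] = xN
    spec["B"][:, 0] = xB
    log2s = np.zeros((n, L + 1))

    for i in range(1, L + 1):
        rx = ods[X[:, i - 1]]  # (n, M)
        dm = np.zeros_like(m)
        dm[:, 1:] = m[:, :-1]
        di = np.zeros_like(ins)
        di[:, 1:] = ins[:, :-1]
        dd_ = np.zeros_like(d)
        dd_[:, 1:] = d[:, :-1]
        mnew = rx * (xB[:, None] * entry_b + dm * pmm_s + di * pim_s + dd_ * pdm_s)
        inew = m * p["mi"] + ins * p["ii"]
        h = np.zeros_like(mnew)
        h[:, 1:] = mnew[:, :-1] * p["md"][:-1]
        dnew = dscan.scan(h) if M > 1 else h
        m, ins, d = mnew, inew, dnew
        xE = m.sum(axis=1)
        xJ = xJ * loop + xE * 0.5
        xC = xC * loop + xE * 0.5
        xN = xN * loop
        xB = (xN + xJ) * move
        # sparse rescale, triggered by the E cell
        mask = xE > RESCALE_TRIGGER
        if np.any(mask):
            sc = np.where(mask, xE, 1.0)
            m /= sc[:, None]
            ins /= sc[:, None]
            d /= sc[:, None]
            xE, xJ, xC, xN, xB = (v / sc for v in (xE, xJ, xC, xN, xB))
            log2s[:, i] = np.log2(sc)
        for nm, v in zip("ENJBC", (xE, xN, xJ, xB, xC)):
            spec[nm][:, i] = v

    with np.errstate(divide="ignore"):
        total = np.log2(xC * move) + log2s.sum(axis=1)
    state = ParserState("fwd", L, spec, log2s, total)
    return total - sp.null.transition_bits(), state


def backward_parser_batch(sp: SearchProfile, X: np.ndarray
                          ) -> tuple[np.ndarray, ParserState]:
    """Sparse-rescaled Backward; same total score as Forward (consistency)."""
    n, L = X.shape
    if L != sp.L:
        sp = sp.with_length(L)
    M = sp.M
    ods = np.exp2(sp.scores).T
    p = _probs(sp)
    entry = sp.entry_vit
    loop, move = sp.loop, sp.move

    # reverse-direction delete scan: bd[k] = pdm[k]*w[k+1] + pdd[k]*bd[k+1];
    # in reversed index j (j=0 is k=M-1) this is bd'[j] = bd'[j-1]*g[j] + h'[j]
    # with g[j] = pdd[M-1-j]
    g = np.zeros(M)
    if M > 1:
        g[1:] = p["dd"][M - 2::-1]
    dscan = _ScanBlocks(g)

    bm = np.zeros((n, M))
    bi = np.zeros((n, M))
    bd = np.zeros((n, M))
    bN = np.zeros(n)
    bB = np.zeros(n)
    bJ = np.zeros(n)
    bC = np.full(n, move)
    bE = 0.5 * bC
    bm[:] = bE[:, None]

    spec = {nm: np.zeros((n, L + 1)) for nm in "ENJBC"}
    for nm, v in zip("ENJBC", (bE, bN, bJ, bB, bC)):
        spec[nm][:, L] = v
    log2s = np.zeros((n, L + 1))

    for i in range(L - 1, -1, -1):
        rx = ods[X[:, i]]          # odds of x_{i+1}, (n, M)
        w = rx * bm                # enter M_{k} and continue, per k
        bB = (entry * w).sum(axis=1)
        w_up = np.zeros_like(w)
        w_up[:, :-1] = w[:, 1:]    # w at k+1, aligned with source k
        bJ = loop * bJ + move * bB
        bC = loop * bC
        bN = loop * bN + move * bB
        bE = 0.5 * (bJ + bC)
        h = p["dm"] * w_up
        bd = dscan.scan(h[:, ::-1])[:, ::-1] if M > 1 else h
        bi_new = p["im"] * w_up + p["ii"] * bi
        bd_up = np.zeros_like(bd)
        bd_up[:, :-1] = bd[:, 1:]
        bm = (p["mm"] * w_up + p["mi"] * bi + p["md"] * bd_up
              + bE[:, None])
        bi = bi_new
        mask = bB > RESCALE_TRIGGER
        if np.any(mask):
            sc = np.where(mask, bB, 1.0)
            bm /= sc[:, None]
            bi /= sc[:, None]
            bd /= sc[:, None]
            bE, bN, bJ, bB, bC = (v / sc for v in (bE, bN, bJ, bB, bC))
            log2s[:, i] = np.log2(sc)
        for nm, v in zip("ENJBC", (bE, bN, bJ, bB, bC)):
            spec[nm][:, i] = v

    with np.errstate(divide="ignore"):
        total = np.log2(bN) + log2s.sum(axis=1)
    state = ParserState("bwd", L, spec, log2s, total)
    return total - sp.null.transition_bits(), state


# ---------------------------------------------------------------------------
# public single-sequence surface
# ---------------------------------------------------------------------------

def forward_score(sp: SearchProfile, seq: str, mode: str = "parser"):
    """Forward bit score; ``mode='parser'`` also returns the ParserState."""
    if mode == "generic":
        return forward_generic(sp, seq)
    if mode != "parser":
        raise ValueError("mode must be 'generic' or 'parser'")
    sc, state = forward_parser_batch(sp, AMINO.encode(seq)[None, :])
    return float(sc[0]), state


def backward_score(sp: SearchProfile, seq: str):
    sc, state = backward_parser_batch(sp, AMINO.encode(seq)[None, :])
    return float(sc[0]), state


def endpoint_posteriors(fwd: ParserState, bwd: ParserState
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities of alignment segment begin/end per position.

    Returns (begin, end), each (n, L): ``begin[:, j]`` is the posterior
    probability that a homologous segment starts at target position j+1
    (1-based), i.e. that the B state was used just before emitting residue
    j+1; ``end[:, j]`` that a segment ends at position j+1 (E usage on that
    row).  Each row of either array sums to the expected segment count.
    """
    if fwd.kind != "fwd" or bwd.kind != "bwd":
        raise ValueError("need one forward and one backward parser state")
    if fwd.L != bwd.L or fwd.n != bwd.n:
        raise ValueError("mismatched forward/backward runs")
    if np.any(np.abs(fwd.total_log2_odds - bwd.total_log2_odds) > 0.05):
        raise ValueError("forward/backward totals disagree; mismatched runs")
    Sf = fwd.cumulative_log2()
    Rb = bwd.cumulative_log2()
    O = fwd.total_log2_odds[:, None]
    with np.errstate(divide="ignore"):
        begin = np.exp2(np.log2(fwd.specials["B"][:, :-1]) + Sf[:, :-1]
                        + np.log2(bwd.specials["B"][:, :-1]) + Rb[:, :-1] - O)
        end = np.exp2(np.log2(fwd.specials["E"][:, 1:]) + Sf[:, 1:]
                      + np.log2(bwd.specials["E"][:, 1:]) + Rb[:, 1:] - O)
    return begin, end
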