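"""Striped data layout and reduced-precision integer profile representations.

Striping assigns DP cell k (1-based, of M cells) to vector (k-1) mod Q, slot
(k-1) div Q, with Q = ceil(M/V) vectors of V cells.  Under this layout the
previous-row diagonal dependency of cell k on cell k-1 is satisfied
vector-wise: targets in vector q read sources from vector q-1, and only the
wrap from the last vector to vector 0 needs a one-slot shift per row.

Two integer reductions are kept on a :class:`ReducedProfile`:

* MSV bytes: unsigned 8-bit costs in units of 1/``scale`` bits (default 3
  units per bit), with a ``base`` offset (default 190) locating the value
  range and a ``bias`` making all residue costs non-negative relative to the
  best residue score.  Saturated at 0 and 255.
* Viterbi words: signed 16-bit scores in units of 1/500 bits with an integer
  offset of 12,000, so representable bit scores span -89.5 .. 41.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile import SearchProfile

SUPPORTED_WIDTHS = (4, 8, 16)

MSV_BASE = 190
MSV_SCALE = 3.0
VIT_SCALE = 500.0
VIT_OFFSET = 12000
WORD_MIN = -32768  # doubles as the -infinity sentinel
WORD_MAX = 32767

#: maximum representable Viterbi-filter bit score: (32767 - 12000) / 500
VIT_MAX_BITS = (WORD_MAX - VIT_OFFSET) / VIT_SCALE


def stripe(values: np.ndarray, V: int, sentinel=0.0) -> np.ndarray:
    """Stripe a length-M array into a (Q, V) matrix; unused slots = sentinel."""
    values = np.asarray(values)
    M = values.shape[-1]
    if M < 1:
        raise ValueError("M must be >= 1")
    Q = -(-M // V)
    out = np.full(values.shape[:-1] + (Q, V), sentinel, dtype=values.dtype)
    idx = np.arange(M)
    out[..., idx % Q, idx // Q] = values[..., idx]
    return out


def unstripe(striped: np.ndarray, M: int) -> np.ndarray:
    """Invert :func:`stripe`, recovering the length-M array."""
    Q, V = striped.shape[-2:]
    if not (V * (Q - 1) < M <= Q * V):
        raise ValueError("striped shape inconsistent with M")
    idx = np.arange(M)
    return striped[..., idx % Q, idx // Q]


def shift_slots(vec: np.ndarray, fill) -> np.ndarray:
    """Right-shift slots by one (slot s <- s-1); slot 0 gets ``fill``.

    This is the per-row wrap operation on the last vector of the previous
    row, aligning cell M-Q+1..M values as diagonal sources for vector 0.
    """
    out = np.empty_like(vec)
    out[..., 1:] = vec[..., :-1]
    out[..., 0] = fill
    return out


def _shifted(a: np.ndarray, fill: float) -> np.ndarray:
    """Array indexed by target position j holding source value at j-1."""
    out = np.empty_like(a)
    out[1:] = a[:-1]
    out[0] = fill
    return out


@dataclass
class ReducedProfile:
    """Striped integer reductions of a search profile's scores.

    The MSV byte costs and Viterbi words depend only on the core model, not
    on the configured target length L; the L-dependent flanking transition
    costs are derived at filter time from the accompanying search profile.
    """

    M: int
    V: int                      # byte vector width (words use V // 2)
    # MSV byte representation
    msv_cost: np.ndarray        # (21, Q8, V) uint8 biased emission costs
    msv_base: int
    msv_scale: float
    msv_bias: int
    tbm_cost: int               # B->Mk entry cost, uniform over k
    tec_cost: int               # E->C / E->J cost (half = 1 bit)
    # Viterbi word representation, striped (Qw, Vw) int16 arrays
    vit_emis: np.ndarray        # (21, Qw, Vw)
    t_bm: np.ndarray
    t_mm: np.ndarray            # shifted: indexed by target, holds source k-1
    t_im: np.ndarray
    t_dm: np.ndarray
    t_mi: np.ndarray
    t_ii: np.ndarray
    t_md: np.ndarray            # source-indexed (used when leaving vector q)
    t_dd: np.ndarray
    vit_scale: float = VIT_SCALE
    vit_offset: int = VIT_OFFSET

    @property
    def Q8(self) -> int:
        return self.msv_cost.shape[1]

    @property
    def Qw(self) -> int:
        return self.vit_emis.shape[1]

    @property
    def Vw(self) -> int:
        return self.vit_emis.shape[2]

    def msv_scores_dequantized(self) -> np.ndarray:
        """Recover (M, 21) float MSV scores to within half a 1/scale unit."""
        costs = unstripe(self.msv_cost.astype(int), self.M)  # (21, M)
        return ((self.msv_bias - costs) / self.msv_scale).T

    def vit_emissions_dequantized(self) -> np.ndarray:
        words = unstripe(self.vit_emis.astype(int), self.M)
        return (words / self.vit_scale).T


def words(bits: np.ndarray | float) -> np.ndarray:
    """Quantize bit scores to 1/500-bit int16 words; -inf maps to WORD_MIN."""
    w = np.where(np.isfinite(bits), np.round(VIT_SCALE * np.asarray(bits, dtype=float)), WORD_MIN)
    return np.clip(w, WORD_MIN, WORD_MAX).astype(np.int32)


def reduce_profile(sp: SearchProfile, V: int = 16) -> ReducedProfile:
    """Quantize and stripe a search profile's scores for the filters."""
    if V not in SUPPORTED_WIDTHS:
        raise ValueError(f"V must be one of {SUPPORTED_WIDTHS}")
    M = sp.M
    s = sp.scores  # (M, 21) bits

    # ---- MSV byte costs -----------------------------------------------------
    # bias offsets costs relative to the maximum residue score, so that every
    # residue cost bias - round(scale*s) is a non-negative byte
    scaled = np.round(MSV_SCALE * s).astype(int)          # (M, 21)
    bias = int(min(255, max(0, scaled.max())))
    cost = np.clip(bias - scaled, 0, 255).astype(np.uint8)  # (M, 21)
    msv_cost = stripe(cost.T, V, sentinel=np.uint8(255))    # (21, Q8, V)

    tbm_cost = int(min(255, round(-MSV_SCALE * sp.entry_msv_bits())))
    tec_cost = int(round(MSV_SCALE * 1.0))  # t(E->C) = 0.5 is -1 bit

    # ---- Viterbi words ------------------------------------------------------
    Vw = max(2, V // 2)
    vit_emis = stripe(words(s).T.astype(np.int32), Vw, sentinel=WORD_MIN).astype(np.int16)

    tb = sp.core_transition_bits()
    NEG = -np.inf
    t_bm = stripe(words(sp.entry_vit_bits()), Vw, sentinel=WORD_MIN)
    t_mm = stripe(words(_shifted(tb["mm"], NEG)), Vw, sentinel=WORD_MIN)
    t_im = stripe(words(_shifted(tb["im"], NEG)), Vw, sentinel=WORD_MIN)
    t_dm = stripe(words(_shifted(tb["dm"], NEG)), Vw, sentinel=WORD_MIN)
    t_mi = stripe(words(tb["mi"]), Vw, sentinel=WORD_MIN)
    t_ii = stripe(words(tb["ii"]), Vw, sentinel=WORD_MIN)
    t_md = stripe(words(tb["md"]), Vw, sentinel=WORD_MIN)
    t_dd = stripe(words(tb["dd"]), Vw, sentinel=WORD_MIN)

    return ReducedProfile(
        M=M, V=V,
        msv_cost=msv_cost, msv_base=MSV_BASE, msv_scale=MSV_SCALE,
        msv_bias=bias, tbm_cost=tbm_cost, tec_cost=tec_cost,
        vit_emis=vit_emis,
        t_bm=t_bm.astype(np.int16), t_mm=t_mm.astype(np.int16),
        t_im=t_im.astype(np.int16), t_dm=t_dm.astype(np.int16),
        t_mi=t_mi.astype(np.int16), t_ii=t_ii.astype(np.int16),
        t_md=t_md.astype(np.int16), t_dd=t_dd.astype(np.int16),
    )
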