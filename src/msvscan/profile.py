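"""Core profile construction and length-model configuration.

A :class:`CoreProfile` is the classic linear profile HMM: per-position match
emission distributions plus match/insert/delete transition probabilities.
A :class:`SearchProfile` wraps a core profile for multihit local search
against a target of a specific length L.  The L-dependent pieces are the
flanking-state transitions (N/C/J loop = L/(L+3), move = 3/(L+3)) and the
geometric null model (loop r = L/(L+1)); the log-odds match scores
s_k(a) = log2 e_k(a)/f_a are L-independent and shared between length
reconfigurations.

Two entry distributions coexist on a search profile:

* Viterbi/Forward entry  t(B->M_k) = 2(M-k+1)/(M(M+1)), which together with
  probability-1 exits from every match state yields a uniform distribution
  over local alignment fragments (i, j), 1 <= i <= j <= M.
* MSV entry 2/(M(M+1)), uniform over k, used by the ungapped filter model in
  which all match-match transitions are treated as probability 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import AMINO, BACKGROUND, K, X_INDEX

GAP_CHARS = set("-.~")

LOG2 = np.log(2.0)


@dataclass
class NullModel:
    """Single-state i.i.d. background model with geometric length distribution."""

    freqs: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    L: int = 400

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (K,) or np.any(self.freqs <= 0):
            raise ValueError("background must be 20 strictly positive frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("background frequencies must sum to 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def r(self) -> float:
        """Geometric loop probability; expected emitted length is exactly L."""
        return self.L / (self.L + 1.0)

    def transition_bits(self) -> float:
        """log2 of the null path's transition probability for a length-L target."""
        L = self.L
        return L * np.log2(self.r) + np.log2(1.0 - self.r)


@dataclass
class CoreProfile:
    """Linear core model: M consensus positions of match/insert/delete states.

    Transition arrays are indexed by 0-based position k (state k+1 in 1-based
    reports).  Entries at the last position are present for shape regularity
    but unused by the local search model, where every match state exits to E
    with probability 1.
    """

    name: str
    match_emissions: np.ndarray  # (M, 20)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    consensus: str = ""

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != K:
            raise ValueError("match_emissions must be (M, 20)")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        for nm in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            setattr(self, nm, np.asarray(getattr(self, nm), dtype=float))
        if not self.consensus:
            self.consensus = "".join(
                AMINO.symbols[i] for i in np.argmax(self.match_emissions, axis=1)
            )
        self.validate()

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def insert_emissions(self) -> np.ndarray:
        """Insert states emit at background frequencies (scores are zero)."""
        return np.broadcast_to(self.background, (self.M, K))

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.match_emissions <= 0):
            raise ValueError("match emissions must be strictly positive")
        if np.max(np.abs(self.match_emissions.sum(axis=1) - 1.0)) > tol:
            raise ValueError("match emission rows must sum to 1")
        m_out = self.t_mm + self.t_mi + self.t_md
        i_out = self.t_im + self.t_ii
        d_out = self.t_dm + self.t_dd
        for nm, row in (("match", m_out), ("insert", i_out), ("delete", d_out)):
            if np.max(np.abs(row - 1.0)) > tol:
                raise ValueError(f"{nm} outgoing transitions must sum to 1")


def match_scores(core: CoreProfile, null: NullModel | None = None) -> np.ndarray:
    """Log-odds match scores s_k(a) = log2(e_k(a) / f_a) in bits, shape (M, 21).

    Column 20 is the wildcard X, which scores 0 bits at every position.
    """
    f = core.background if null is None else null.freqs
    if np.any(f <= 0):
        raise ValueError("background frequencies must be strictly positive")
    s = np.log2(core.match_emissions / f)
    return np.hstack([s, np.zeros((core.M, 1))])


def relative_entropy(core: CoreProfile, null: NullModel | None = None) -> float:
    """Mean per-position KL divergence of match emissions from background, bits."""
    f = core.background if null is None else null.freqs
    e = core.match_emissions
    return float(np.mean(np.sum(e * np.log2(e / f), axis=1)))


@dataclass
class SearchProfile:
    """A core profile configured for multihit local search at target length L."""

    core: CoreProfile
    L: int
    scores: np.ndarray            # (M, 21) bits, X column zero
    entry_vit: np.ndarray         # t(B->M_k) = 2(M-k+1)/(M(M+1))
    entry_msv: np.ndarray         # uniform 2/(M(M+1))
    null: NullModel

    @property
    def M(self) -> int:
        return self.core.M

    # --- L-dependent flanking-state parameters -------------------------------
    @property
    def loop(self) -> float:
        return self.L / (self.L + 3.0)

    @property
    def move(self) -> float:
        return 3.0 / (self.L + 3.0)

    @property
    def loop_bits(self) -> float:
        return float(np.log2(self.loop))

    @property
    def move_bits(self) -> float:
        return float(np.log2(self.move))

    t_ej: float = 0.5
    t_ec: float = 0.5

    def with_length(self, L: int) -> "SearchProfile":
        """Reconfigure the length model; score matrices are shared, not copied."""
        if L == self.L:
            return self
        if L < 1:
            raise ValueError("L must be >= 1")
        return replace(self, L=L, null=NullModel(self.null.freqs, L))

    # --- log2 transition scores for the gapped model -------------------------
    def core_transition_bits(self) -> dict[str, np.ndarray]:
        c = self.core
        with np.errstate(divide="ignore"):
            return {nm: np.log2(getattr(c, "t_" + nm)) for nm in
                    ("mm", "mi", "md", "im", "ii", "dm", "dd")}

    def entry_vit_bits(self) -> np.ndarray:
        return np.log2(self.entry_vit)

    def entry_msv_bits(self) -> float:
        return float(np.log2(self.entry_msv[0]))


def configure_length(core: CoreProfile, L: int) -> SearchProfile:
    """Build a multihit-local search profile for a length-L target."""
    if L < 1:
        raise ValueError("L must be >= 1")
    M = core.M
    k = np.arange(1, M + 1)
    entry_vit = 2.0 * (M - k + 1) / (M * (M + 1.0))
    entry_msv = np.full(M, 2.0 / (M * (M + 1.0)))
    null = NullModel(core.background, L)
    return SearchProfile(
        core=core,
        L=L,
        scores=match_scores(core, null),
        entry_vit=entry_vit,
        entry_msv=entry_msv,
        null=null,
    )


# --------------------------------------------------------------------------
# profile construction from a multiple alignment
# --------------------------------------------------------------------------

# transition pseudocounts: mild gap-open, geometric-ish gap extension
_T_PSEUDO = {
    "m": np.array([1.0, 0.1, 0.1]),   # M -> M, I, D
    "i": np.array([0.6, 0.4]),        # I -> M, I
    "d": np.array([0.6, 0.4]),        # D -> M, D
}


def consensus_columns(rows: list[str]) -> np.ndarray:
    """Boolean mask of consensus columns: gap fraction < 0.5."""
    arr = np.array([[c in GAP_CHARS for c in r] for r in rows])
    return arr.mean(axis=0) < 0.5


def build_from_msa(
    msa,
    pseudocount_weight: float = 1.0,
    entropy_target: float | None = None,
    name: str = "query",
    reference_line: str | None = None,
    background: np.ndarray | None = None,
) -> CoreProfile:
    """Build a core profile from an aligned set of sequences.

    Columns with less than 50% gap characters become consensus (match)
    columns, unless ``reference_line`` (a Stockholm-style #=GC RF annotation)
    marks them explicitly.  Emissions get Laplace-style background-scaled
    pseudocounts of total weight ``pseudocount_weight * 20``; with
    ``entropy_target`` set, observed counts are scaled down by a factor found
    by bisection until the mean relative entropy is within 0.01 bits of the
    target (counts already below target are kept as is).
    """
    rows = [str(r) for r in msa]
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("ragged alignment")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    f = BACKGROUND if background is None else np.asarray(background, dtype=float)

    if reference_line is not None:
        if len(reference_line) != ncol:
            raise ValueError("reference annotation length mismatch")
        is_cons = np.array([c not in GAP_CHARS for c in reference_line])
    else:
        is_cons = consensus_columns(rows)
    M = int(is_cons.sum())
    if M == 0:
        raise ValueError("alignment has no consensus columns")

    cons_idx = np.flatnonzero(is_cons)
    # emission counts over consensus columns (X / degenerate residues ignored)
    counts = np.zeros((M, K))
    # transition counts
    tc = {"mm": 0.0, "mi": 0.0, "md": 0.0, "im": 0.0, "ii": 0.0,
          "dm": 0.0, "dd": 0.0}
    tcounts = {nm: np.zeros(M) for nm in tc}

    for row in rows:
        enc = AMINO.encode(row)
        gaps = np.array([c in GAP_CHARS for c in row])
        # per-column state of this sequence: M, D (consensus) or I (insert)
        for j, col in enumerate(cons_idx):
            if not gaps[col] and enc[col] != X_INDEX:
                counts[j, enc[col]] += 1.0
        # walk the state path to count transitions between consensus positions
        prev_state = None  # (kind, position)
        for col in range(ncol):
            if is_cons[col]:
                kind = "d" if gaps[col] else "m"
                k_pos = int(np.searchsorted(cons_idx, col))
            else:
                if gaps[col]:
                    continue
                kind = "i"
                k_pos = int(np.searchsorted(cons_idx, col, side="right")) - 1
                if k_pos < 0:
                    continue  # insert before first consensus column: N-flank
            if prev_state is not None:
                pk, pp = prev_state
                key = pk + kind
                if key in tcounts:
                    tcounts[key][pp] += 1.0
            prev_state = (kind, k_pos)

    pseudo = pseudocount_weight * K * f

    def emissions_for(weight: float) -> np.ndarray:
        e = weight * counts + pseudo
        return e / e.sum(axis=1, keepdims=True)

    weight = 1.0
    if entropy_target is not None:
        core_h = lambda w: float(np.mean(np.sum(
            emissions_for(w) * np.log2(emissions_for(w) / f), axis=1)))
        if core_h(1.0) > entropy_target:
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if core_h(mid) > entropy_target:
                    hi = mid
                else:
                    lo = mid
                if abs(core_h(mid) - entropy_target) <= 0.01:
                    weight = mid
                    break
            else:
                weight = 0.5 * (lo + hi)

    emis = emissions_for(weight)

    m_c = np.stack([tcounts["mm"], tcounts["mi"], tcounts["md"]], axis=1) + _T_PSEUDO["m"]
    i_c = np.stack([tcounts["im"], tcounts["ii"]], axis=1) + _T_PSEUDO["i"]
    d_c = np.stack([tcounts["dm"], tcounts["dd"]], axis=1) + _T_PSEUDO["d"]
    m_c /= m_c.sum(axis=1, keepdims=True)
    i_c /= i_c.sum(axis=1, keepdims=True)
    d_c /= d_c.sum(axis=1, keepdims=True)

    return CoreProfile(
        name=name,
        match_emissions=emis,
        t_mm=m_c[:, 0], t_mi=m_c[:, 1], t_md=m_c[:, 2],
        t_im=i_c[:, 0], t_ii=i_c[:, 1],
        t_dm=d_c[:, 0], t_dd=d_c[:, 1],
        background=f.copy(),
    )
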