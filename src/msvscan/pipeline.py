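"""The staged acceleration pipeline: MSV -> bias -> Viterbi -> Forward.

Each model/target comparison runs through a cascade of score filters, each
thresholded on the P-value of its log-odds score: the MSV ungapped filter
(default P < 0.02), a biased-composition retest of the MSV score, the
16-bit Viterbi filter (P < 0.001), and the full Forward parser (P < 1e-5).
A comparison is accepted or rejected as a whole at each step; reduced-
precision scores that overflow their representation count as passing.
E-values are Forward P-values times the number of targets searched.

``max_mode`` disables all filters and computes Forward for every target,
which bounds the sensitivity cost of the filters (hits reported with
filters on are always a subset of max-mode hits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO, encode_seqs
from .fwdback import forward_parser_batch
from .msv import msv_filter_batch
from .profile import SearchProfile
from .stats import Calibration, exp_tail_pvalue, gumbel_pvalue
from .striped import ReducedProfile
from .viterbi import viterbi_filter_batch

STAGES = ("msv_rejected", "bias_rejected", "vit_rejected", "fwd_rejected",
          "reported")


@dataclass
class PipelineConfig:
    F1: float = 0.02      # MSV filter P-value threshold
    F2: float = 0.001     # Viterbi filter threshold
    F3: float = 1e-5      # Forward threshold
    bias_filter: bool = True
    max_mode: bool = False
    report_evalue_max: float = 10.0

    def __post_init__(self) -> None:
        if self.max_mode:
            return
        if not (0 < self.F3 <= self.F2 <= self.F1 <= 1):
            raise ValueError("thresholds must satisfy 0 < F3 <= F2 <= F1 <= 1")


@dataclass
class Hit:
    target: str
    L: int
    stage_reached: str
    msv_bits: float | None = None
    msv_p: float | None = None
    bias_p: float | None = None
    vit_bits: float | None = None
    vit_p: float | None = None
    fwd_bits: float | None = None
    fwd_p: float | None = None
    evalue: float | None = None


@dataclass
class PipelineStats:
    n_targets: int = 0
    n_pass_msv: int = 0
    n_pass_bias: int = 0
    n_pass_vit: int = 0
    n_pass_fwd: int = 0
    n_reported: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# bias filter
# ---------------------------------------------------------------------------

#: hand-tuned transitions of the two-state composition HMM
BIAS_T = np.array([[0.99, 0.01],
                   [0.05, 0.95]])
BIAS_START = np.array([0.99, 0.01])


def profile_composition(sp: SearchProfile) -> np.ndarray:
    """Average residue composition of the query profile's match states."""
    return sp.core.match_emissions.mean(axis=0)


def bias_filter_batch(sp: SearchProfile, X: np.ndarray,
                      msv_bits: np.ndarray) -> np.ndarray:
    """MSV bit scores re-based against a biased-composition null model.

    The alternative null is a fully connected two-state HMM: one state emits
    the average protein composition, the other the average composition of
    the query profile.  Its Forward log-odds versus the standard null (both
    wrapped in the same geometric length model, which cancels) is the bias
    correction, subtracted from the MSV score when positive — the correction
    never raises a score.
    """
    n, L = X.shape
    comp = profile_composition(sp)
    f = sp.null.freqs
    # emission odds ratios per state, X residue is neutral in both
    odds = np.ones((21, 2))
    odds[:20, 1] = comp / f
    v = np.broadcast_to(BIAS_START, (n, 2)).copy()
    logscale = np.zeros(n)
    for i in range(L):
        v = (v @ BIAS_T) * odds[X[:, i]]
        tot = v.sum(axis=1)
        logscale += np.log2(tot)
        v /= tot[:, None]
    bias_bits = logscale + np.log2(v.sum(axis=1))
    return msv_bits - np.maximum(0.0, bias_bits)


# ---------------------------------------------------------------------------
# pipeline proper
# ---------------------------------------------------------------------------

def _pipeline_group(sp: SearchProfile, rp: ReducedProfile, cal: Calibration,
                    X: np.ndarray, ids: list[str], cfg: PipelineConfig,
                    n_db: int, stats: PipelineStats) -> list[Hit]:
    """Run the cascade for one same-length batch of targets."""
    n, L = X.shape
    spL = sp.with_length(L)
    hits = [Hit(t, L, "msv_rejected") for t in ids]
    stats.n_targets += n

    if cfg.max_mode:
        fwd_sc, _ = forward_parser_batch(spL, X)
        fwd_p = exp_tail_pvalue(fwd_sc, cal.fwd)
        stats.n_pass_msv += n
        stats.n_pass_bias += n
        stats.n_pass_vit += n
        for j, h in enumerate(hits):
            h.fwd_bits = float(fwd_sc[j])
            h.fwd_p = float(fwd_p[j])
            h.evalue = float(fwd_p[j] * n_db)
            h.stage_reached = "reported"
        stats.n_pass_fwd += n
        return hits

    # --- MSV filter ---
    msv_sc, over, _ = msv_filter_batch(rp, spL, X)
    msv_p = gumbel_pvalue(msv_sc, cal.msv)
    alive = (msv_p < cfg.F1) | over
    for j, h in enumerate(hits):
        h.msv_bits, h.msv_p = float(msv_sc[j]), float(msv_p[j])
    stats.n_pass_msv += int(alive.sum())

    # --- bias filter: rescore MSV against the composition null, retest ---
    if cfg.bias_filter and np.any(alive):
        idx = np.flatnonzero(alive)
        corr = bias_filter_batch(spL, X[idx], msv_sc[idx])
        bias_p = gumbel_pvalue(corr, cal.msv)
        keep = (bias_p < cfg.F1) | over[idx]
        for jj, j in enumerate(idx):
            hits[j].bias_p = float(bias_p[jj])
            if not keep[jj]:
                hits[j].stage_reached = "bias_rejected"
        alive[idx] = keep
    stats.n_pass_bias += int(alive.sum())

    # --- Viterbi filter ---
    if np.any(alive):
        idx = np.flatnonzero(alive)
        vit_sc, vover = viterbi_filter_batch(rp, spL, X[idx])
        vit_p = gumbel_pvalue(vit_sc, cal.vit)
        keep = (vit_p < cfg.F2) | vover
        for jj, j in enumerate(idx):
            hits[j].vit_bits = float(vit_sc[jj])
            hits[j].vit_p = float(vit_p[jj])
            hits[j].stage_reached = "vit_rejected" if not keep[jj] else hits[j].stage_reached
        alive[idx] = keep
    stats.n_pass_vit += int(alive.sum())

    # --- Forward ---
    if np.any(alive):
        idx = np.flatnonzero(alive)
        fwd_sc, _ = forward_parser_batch(spL, X[idx])
        fwd_p = exp_tail_pvalue(fwd_sc, cal.fwd)
        keep = fwd_p < cfg.F3
        for jj, j in enumerate(idx):
            hits[j].fwd_bits = float(fwd_sc[jj])
            hits[j].fwd_p = float(fwd_p[jj])
            hits[j].evalue = float(fwd_p[jj] * n_db)
            hits[j].stage_reached = "reported" if keep[jj] else "fwd_rejected"
        alive[idx] = keep
    stats.n_pass_fwd += int(alive.sum())

    # mark targets rejected at MSV explicitly (default stage already set)
    return hits


def run_pipeline(sp: SearchProfile, rp: ReducedProfile, cal: Calibration,
                 seq: str, cfg: PipelineConfig | None = None,
                 target_id: str = "target", n_db: int = 1) -> Hit:
    """One model/sequence comparison through the staged pipeline."""
    cfg = cfg or PipelineConfig()
    stats = PipelineStats()
    X = AMINO.encode(seq)[None, :]
    return _pipeline_group(sp, rp, cal, X, [target_id], cfg, n_db, stats)[0]


def search_db(sp: SearchProfile, rp: ReducedProfile, cal: Calibration,
              targets: list[tuple[str, str]],
              cfg: PipelineConfig | None = None
              ) -> tuple[list[Hit], PipelineStats]:
    """Search a target database; returns all hits (reported ones first,
    sorted by E-value ascending) plus per-stage pass counts.

    The profile's length model is reconfigured to each target's length;
    targets are processed in same-length batches.
    """
    cfg = cfg or PipelineConfig()
    if not targets:
        raise ValueError("empty target database")
    stats = PipelineStats()
    n_db = len(targets)

    groups: dict[int, list[int]] = {}
    for i, (_, seq) in enumerate(targets):
        groups.setdefault(len(seq), []).append(i)

    all_hits: list[Hit | None] = [None] * n_db
    for L, idxs in sorted(groups.items()):
        X = encode_seqs([targets[i][1] for i in idxs])
        ids = [targets[i][0] for i in idxs]
        for h, i in zip(_pipeline_group(sp, rp, cal, X, ids, cfg, n_db, stats), idxs):
            all_hits[i] = h

    reported = [h for h in all_hits
                if h.stage_reached == "reported"
                and h.evalue is not None and h.evalue <= cfg.report_evalue_max]
    reported.sort(key=lambda h: h.evalue)
    stats.n_reported = len(reported)
    rep_ids = set(map(id, reported))
    rest = [h for h in all_hits if id(h) not in rep_ids]
    return reported + rest, stats
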