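"""Score statistics: Gumbel / exponential-tail P-values and calibration.

Optimal-alignment bit scores (MSV and Viterbi) of i.i.d. null sequences are
conjectured to follow Gumbel distributions with a fixed slope lambda = ln 2
per bit; the high tail of Forward bit scores follows an exponential of the
same slope.  Finite model length inflates the observed slope for
low-relative-entropy models (edge effect), corrected ad hoc as

    lambda_hat = ln 2 + 1.44 / (M * H)

with M the model length and H the relative entropy per match position in
bits.  Given the slope, the Gumbel location mu is fitted by maximum
likelihood to a small simulation (~200 random sequences), which is the whole
of model calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .profile import SearchProfile, relative_entropy

LN2 = float(np.log(2.0))


@dataclass
class GumbelParams:
    """Location/slope of a Gumbel score distribution (bits, 1/bits)."""

    mu: float
    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel slope must be positive")


@dataclass
class ExpTailParams:
    """Exponential upper-tail description for Forward scores."""

    tau: float
    lam: float
    tailmass: float = 0.04

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("slope must be positive")
        if not (0 < self.tailmass <= 1):
            raise ValueError("tailmass must be in (0, 1]")


def gumbel_pvalue(x, p: GumbelParams):
    """P(S > x) under Gumbel(mu, lam); strictly decreasing, in (0, 1)."""
    with np.errstate(over="ignore"):  # exp overflow far left -> P = 1 exactly
        return -np.expm1(-np.exp(-p.lam * (np.asarray(x, dtype=float) - p.mu)))


def exp_tail_pvalue(x, p: ExpTailParams):
    """P(S > x) = tailmass * exp(-lam (x - tau)), clamped to <= 1."""
    return np.minimum(1.0, p.tailmass * np.exp(-p.lam * (np.asarray(x, dtype=float) - p.tau)))


def overflow_bound(t: float) -> float:
    """Conservative bound P(S >= t) <= 2^-t for log-odds bit scores.

    Justifies treating saturation at the top of a reduced-precision range as
    an automatic filter pass.
    """
    return float(2.0 ** (-t))


def edge_corrected_lambda(M: int, H: float) -> float:
    """Edge-effect-corrected Gumbel slope: ln2 + 1.44/(M*H), 1/bits."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if H <= 0:
        raise ValueError("relative entropy must be positive")
    return LN2 + 1.44 / (M * H)


def fit_gumbel_location(scores, lam: float) -> float:
    """Closed-form ML Gumbel location given a known slope.

    mu = -(1/lam) * ln( mean( exp(-lam * x_i) ) ), computed with a shift for
    numerical stability.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("no scores")
    if lam <= 0:
        raise ValueError("slope must be positive")
    m = x.min()
    return float(m - np.log(np.mean(np.exp(-lam * (x - m)))) / lam)


def fit_gumbel_ml(scores) -> GumbelParams:
    """Joint ML Gumbel fit via root-finding on the profile likelihood.

    The slope solves 1/lam = mean(x) - sum(x exp(-lam x))/sum(exp(-lam x));
    the location then follows from :func:`fit_gumbel_location`.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 scores")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) scores")
    xc = x - x.mean()  # shift-invariant profile equation

    def eq(lam: float) -> float:
        w = np.exp(-lam * (xc - xc.min()))
        return 1.0 / lam - xc.mean() + np.sum(xc * w) / np.sum(w)

    lo, hi = 1e-4, 1.0
    while eq(hi) > 0 and hi < 1e4:
        hi *= 2.0
    lam = float(brentq(eq, lo, hi, xtol=1e-10))
    return GumbelParams(mu=fit_gumbel_location(x, lam), lam=lam)


@dataclass
class Calibration:
    """Fitted score statistics for one profile (MSV, Viterbi, Forward)."""

    msv: GumbelParams
    vit: GumbelParams
    fwd: ExpTailParams
    n: int = 200
    Lcal: int = 400
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "msv_mu": self.msv.mu, "msv_lambda": self.msv.lam,
            "vit_mu": self.vit.mu, "vit_lambda": self.vit.lam,
            "fwd_tau": self.fwd.tau, "fwd_lambda": self.fwd.lam,
            "fwd_tailmass": self.fwd.tailmass,
            "n": self.n, "Lcal": self.Lcal, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            msv=GumbelParams(d["msv_mu"], d["msv_lambda"]),
            vit=GumbelParams(d["vit_mu"], d["vit_lambda"]),
            fwd=ExpTailParams(d["fwd_tau"], d["fwd_lambda"], d["fwd_tailmass"]),
            n=int(d["n"]), Lcal=int(d["Lcal"]), seed=int(d["seed"]),
        )


def sample_iid_batch(freqs: np.ndarray, n: int, L: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n, L) batch of encoded i.i.d. background sequences."""
    return rng.choice(len(freqs), size=(n, L), p=freqs).astype(np.int8)


def calibrate(sp: SearchProfile, rp=None, n: int = 200, Lcal: int = 400,
              seed: int = 0, tailmass: float = 0.04) -> Calibration:
    """Calibrate score statistics from a small null-sequence simulation.

    Scores ``n`` i.i.d. length-``Lcal`` background sequences with the same
    reduced-precision filters and Forward parser used at search time, fixes
    the slope at the edge-corrected lambda, and fits locations by ML.
    Deterministic given ``seed``.
    """
    from .msv import msv_filter_batch
    from .striped import reduce_profile
    from .viterbi import viterbi_filter_batch
    from .fwdback import forward_parser_batch

    if n < 10:
        raise ValueError("calibration needs at least 10 sequences")
    if rp is None:
        rp = reduce_profile(sp)
    rng = np.random.default_rng(seed)
    X = sample_iid_batch(sp.null.freqs, n, Lcal, rng)
    spc = sp.with_length(Lcal)

    lam = edge_corrected_lambda(sp.M, relative_entropy(sp.core, spc.null))
    msv_sc, _, _ = msv_filter_batch(rp, spc, X)
    vit_sc, _ = viterbi_filter_batch(rp, spc, X)
    fwd_sc, _ = forward_parser_batch(spc, X)

    # fixed-slope ML location for the exponential tail is the tail minimum,
    # i.e. the empirical (1 - tailmass) quantile
    tau = float(np.quantile(fwd_sc, 1.0 - tailmass))
    return Calibration(
        msv=GumbelParams(fit_gumbel_location(msv_sc, lam), lam),
        vit=GumbelParams(fit_gumbel_location(vit_sc, lam), lam),
        fwd=ExpTailParams(tau, lam, tailmass),
        n=n, Lcal=Lcal, seed=seed,
    )
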