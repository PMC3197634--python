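# Methods

This note records the model as implemented, the numerical choices, what the
synthetic-data generators do and do not emulate, and the known limitations.

## The search model

A core profile has M consensus positions with match emissions e_k(a) over
the 20 amino acids, insert emissions fixed at the background f_a, and
per-position transitions t(M→M), t(M→I), t(M→D), t(I→M), t(I→I), t(D→M),
t(D→D). Degenerate residue codes map to X, which scores 0 bits everywhere.

Configured for a target of length L, the multihit local model adds:

- N/C/J flanking states emitting at background, with loop probability
  L/(L+3) and move probability 3/(L+3);
- a geometric null with loop r = L/(L+1), so the expected null length is L;
  its transition score L·log2 r + log2(1−r) is subtracted at termination;
- entry t(B→M_k) = 2(M−k+1)/(M(M+1)) for Viterbi/Forward;
- exit from every match state to E with probability 1 (the implicit
  fragment model: together with the entry this puts uniform mass on
  fragments i ≤ j);
- t(E→J) = t(E→C) = 0.5 (multihit).

Segments begin and end in match states: E collects from M states only, not
from D. This convention is applied identically in the serial DPs, the
reduced-precision filters, the parsers, and the brute-force enumerator, and
the enumeration oracles are the ground truth for all of them. The MSV view
of the same profile keeps only match states, scores match–match transitions
as zero, and uses the uniform per-fragment entry 2/(M(M+1)).

## Reduced precision

MSV bytes: scores are scaled to 1/3-bit units; residue costs are stored as
bias − round(3·s_k(a)) with bias = round(3·max s), so all costs are
non-negative bytes, saturated at 255. The DP value range is anchored at base
190. N/C/J loops cost zero in the recursion; the constant −3/ln 2 ≈ −4.33
bits (the large-L limit of L·log2(L/(L+3))) is added at termination, and the
null transition score is subtracted exactly. A row whose E value reaches
255 − bias flags overflow, which counts as passing any filter (justified by
the bound P(S ≥ t) ≤ 2^−t). The striped layout (cell k → vector
(k−1) mod Q, slot (k−1) div Q, Q = ⌈M/V⌉) is emulated on integer arrays with
explicit clamping; it is bit-identical to the scalar byte DP by test, and
the emulated vector width V ∈ {4, 8, 16} (default 16).

Viterbi words: scores in 1/500-bit units with integer offset 12,000
(representable −89.5..41.5 bits), saturated signed 16-bit. The striped
delete chain is resolved by Farrar's lazy-F scheme: a pessimistic first pass
carries delete candidates vector to vector, then a fixed-point loop (at most
V passes) propagates chains across the slot wrap. The tiny per-row N/C/J
loop cost is applied as error-diffused integer increments whose cumulative
sum tracks 500·i·log2(L/(L+3)) within half a unit at every row; without
this, plain per-row rounding drifts ~0.3 bits over a 400-residue target.
Filter and float scores agree within 0.02 bits in practice (0.1 bits is the
tested bound).

## Forward/Backward

The generic reference works in log2 space with exact log-sum-exp; a
16,000-entry lookup table at 1/1000-bit resolution (max error below half a
step) is provided for the classic table-driven form and used only in
fidelity tests.

The parser works in the odds-ratio domain. Row values are renormalized by
the row's E value when it exceeds 1e10 (forward; the backward parser
mirrors this on its B value), and the log2 scale factors are accumulated;
the sum of logged scales plus the final stored value reproduces the total
exactly. The within-row delete recurrence d(k) = d(k−1)·t(D→D) + m(k−1)·
t(M→D) is evaluated by a blocked closed form: blocks are cut where the
cumulative delete-extension product would fall below e^−400 (or at exact
zeros), so no intermediate can underflow even for near-1 delete extensions
across a 500-state model. Parser and generic totals agree within 1e-3 bits
on randomized and adversarial (long-deletion, biased-composition) suites.

The parser stores the special-state columns (E, N, J, B, C), which is
enough for endpoint posterior decoding: P(segment starts after position i)
= f_B(i)·b_B(i)/O with the scale bookkeeping applied in log space. The
posterior B and E masses are equal and equal the exact expected segment
count computed by path enumeration on tiny instances. Note the multihit
model forces at least one segment per path, so the expected segment count
on pure background sequences is ≥ 1 by construction — it is a baseline, not
a detection signal.

## Score statistics and calibration

MSV and Viterbi null scores are treated as Gumbel with slope fixed at the
edge-corrected λ̂ = ln 2 + 1.44/(M·H); the location is the closed-form
fixed-slope ML estimate from n = 200 i.i.d. sequences of length 400, scored
with the same reduced-precision filters used at search time (so filter
quantization is absorbed into the location). ML joint fits of simulated
score distributions recover slopes within the 0.55–0.85 band around ln 2,
and the observed filter pass fraction at P < 0.02 is correct within
two-fold (the headline calibration check).

Forward scores use an exponential upper tail of the same slope with
tailmass 0.04; the fixed-slope ML location on the top 4% of calibration
scores is their minimum, i.e. the empirical 96% quantile. Two caveats,
both visible in the tests: (i) with 200 calibration sequences the tau
estimate carries ~0.6 bits of sampling noise, so single-calibration
P-values can be off by ~2× near the tail (the tests average over
calibration replicates to check systematic accuracy); (ii) in this
implementation the empirical Forward null tail decays at ~0.55/bit,
shallower than the conjectured edge-corrected slope, so deep-tail Forward
P-values are approximate — adequate for filtering and ranking, not for
precise deep-tail error rates.

## Pipeline

Stage order and defaults: MSV (P < 0.02) → bias-corrected MSV retest
(P < 0.02) → Viterbi filter (P < 0.001) → Forward (P < 1e-5); overflowed
filter scores pass unconditionally; E-value = Forward P × number of
targets. The Forward threshold default of 1e-5 is a package choice sitting
between the Viterbi threshold and reporting thresholds; it is configurable.
The bias filter's two-state HMM uses transitions (stay-background 0.99,
go-bias 0.01, stay-bias 0.95, go-background 0.05) and start (0.99, 0.01) —
hand-tuned values with no canonical source; its correction is clamped to
never increase a score, and it never affects the reported Forward score.
The profile's length model is reconfigured to each target's L before
scoring; score matrices are shared across reconfigurations. `max_mode`
disables all filters and is the reference against which filter losses are
measured (≤ 1% of E ≤ 1e-4 hits lost on a 10,000-decoy benchmark).

Domain-level postprocessing (envelope definition, per-domain scores,
alignments, the null2 composition correction) is out of scope; endpoint
posteriors are the provided substitute.

## Synthetic data

`synthetic_profile` draws per-position emissions from a Dirichlet around
the background (concentration 4, giving raw relative entropies near 1.6
bits/position with realistic position-to-position spread) and then mixes
all positions toward the background by a single bisection-tuned weight to
hit an entropy target (default 0.6 bits/position) — the same one-scalar
re-weighting that entropy-weighted model building applies to counts. The
continuous spread matters: emission grids with only a few distinct score
values alias against the 1/3-bit quantization and produce spurious
systematic roundoff bias that real family models do not show.

`synthetic_family_msa` builds ungapped alignments with explicit cluster
structure (independent ancestors per cluster, point substitutions within),
which exercises the profmark clustering logic but does not emulate indels,
fragmentary sequences beyond the constructed case, phylogenetic
autocorrelation, or repetitive/low-complexity sequence. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
on idealized data, not robustness to every pathology of real proteins —
biased-composition behavior is probed separately with skewed-frequency
generators.

The profmark constructor follows the seven-step recipe (degeneracies → X;
fragment removal below 70% of the mean unaligned length; 25% single-linkage
query split; 50% clustering of the remainder; one random domain per
cluster; embedding with total length drawn from the database length
distribution conditioned to fit, by rejection sampling; decoys copying
positive segment structures). Identity constraints are re-verified post hoc
on every build. Without a backing sequence database, lengths come from a
log-normal surrogate (median 350, σ_log 0.6). Embedding positions are
uniform over order-preserving arrangements (stars-and-bars over the spare
length). The di-residue shuffle is a seeded Hierholzer Euler-circuit walk,
exact on the pair-count matrix.

## Problem sizes

Default simulation sizes: calibration n = 200 at L = 400; filter-fraction
experiment 50,000 sequences; roundoff experiment 1,000; the pipeline
benchmark 10,000 decoys. The scoring kernels are vectorized across
sequences (all same-length targets advance through one striped recursion),
which is what makes these sizes interactive on a single CPU.

## Limitations

- Local multihit mode only; no glocal alignment.
- No Dirichlet-mixture priors or per-sequence weighting in profile
  building (background-scaled pseudocounts plus the scalar entropy weight).
- No official HMMER file-format compatibility; the profile format is this
  package's own documented text format.
- Forward deep-tail P-values are approximate (see above).
- Scores only from the filters (no tracebacks/alignments).
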