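"""Synthetic sequence generation and benchmark construction.

This module supplies the randomized inputs everything else is exercised on:
i.i.d. background sequences, composition-preserving shufflers, synthetic
profiles and family alignments, the profmark benchmark constructor
(query/test splitting by identity clustering, domain embedding, matched
decoys), and the calibration/roundoff simulation drivers.

All generators are deterministic under a seed; conservation properties
(residue multisets, di-residue count matrices, decoy segment-length copying)
hold exactly by construction and are re-verified on every built benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO, BACKGROUND, K
from .io import MSA, SequenceRecord
from .profile import CoreProfile, SearchProfile, relative_entropy
from .stats import Calibration, gumbel_pvalue, sample_iid_batch

# surrogate length distribution used when no real sequence database backs
# the benchmark: log-normal, median 350, sigma_log 0.6
LOGNORMAL_MEDIAN = 350.0
LOGNORMAL_SIGMA = 0.6


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def sample_iid(L: int, freqs: np.ndarray | None = None,
               seed: int | np.random.Generator = 0) -> str:
    """Length-L i.i.d. sequence from the background residue frequencies."""
    if L < 1:
        raise ValueError("L must be >= 1")
    f = BACKGROUND if freqs is None else np.asarray(freqs, dtype=float)
    if f.shape != (K,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
        raise ValueError("invalid frequency vector")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return AMINO.decode(rng.choice(K, size=L, p=f))


def shuffle_seq(seq: str, mode: str = "mono",
                seed: int | np.random.Generator = 0) -> str:
    """Shuffle a sequence preserving composition.

    mono: permute residues (0th-order composition preserved exactly);
    di: random Eulerian rearrangement preserving the di-residue count matrix;
    reverse: exact reversal.
    """
    if not seq:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mode == "reverse":
        return seq[::-1]
    if mode == "mono":
        chars = np.array(list(seq))
        rng.shuffle(chars)
        return "".join(chars)
    if mode == "di":
        return _di_shuffle(seq, rng)
    raise ValueError("mode must be 'mono', 'di', or 'reverse'")


def _di_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Euler-path shuffle: random walk over the exact di-residue multigraph.

    An auxiliary edge from the last to the first residue closes the walk
    into a circuit; Hierholzer's algorithm with seeded random edge order
    yields a circuit which, broken at the auxiliary edge, is a permuted
    sequence with the original's di-residue counts.
    """
    if len(seq) < 2:
        raise ValueError("di-shuffle needs length >= 2")
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    adj.setdefault(seq[-1], []).append(seq[0])  # auxiliary closing edge
    for v in adj:
        rng.shuffle(adj[v])
    # Hierholzer circuit from the first residue
    stack = [seq[0]]
    circuit: list[str] = []
    ptr = {v: 0 for v in adj}
    while stack:
        v = stack[-1]
        if ptr[v] < len(adj[v]):
            stack.append(adj[v][ptr[v]])
            ptr[v] += 1
        else:
            circuit.append(stack.pop())
    circuit.reverse()  # closed walk: starts and ends at seq[0]
    # break at an occurrence of the auxiliary edge (seq[-1] -> seq[0])
    for i in range(len(circuit) - 1):
        if circuit[i] == seq[-1] and circuit[i + 1] == seq[0]:
            rotated = circuit[i + 1:-1] + circuit[:i + 1]
            return "".join(rotated)
    raise RuntimeError("no Eulerian circuit found")  # pragma: no cover


def dinucleotide_counts(seq: str) -> dict[tuple[str, str], int]:
    out: dict[tuple[str, str], int] = {}
    for a, b in zip(seq, seq[1:]):
        out[(a, b)] = out.get((a, b), 0) + 1
    return out


# ---------------------------------------------------------------------------
# identity and clustering
# ---------------------------------------------------------------------------

def percent_identity(row_a: str, row_b: str) -> float:
    """Identities / shorter unaligned length, for one aligned row pair."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    GAP = set("-.~")
    ident = sum(1 for a, b in zip(row_a, row_b)
                if a not in GAP and b not in GAP and a == b)
    la = sum(1 for a in row_a if a not in GAP)
    lb = sum(1 for b in row_b if b not in GAP)
    if la == 0 or lb == 0:
        raise ValueError("zero-length sequence")
    return ident / min(la, lb)


def single_linkage(n: int, identity, threshold: float) -> list[list[int]]:
    """Single-linkage clusters of items 0..n-1: link pairs with
    identity(i, j) > threshold; returns clusters sorted by decreasing size.
    """
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if identity(i, j) > threshold:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


# ---------------------------------------------------------------------------
# synthetic profiles and families
# ---------------------------------------------------------------------------

def synthetic_profile(M: int, seed: int = 0,
                      entropy_target: float | None = 0.6,
                      name: str = "synthetic") -> CoreProfile:
    """Random core profile with a controlled relative entropy per position.

    Per-position emissions are Dirichlet draws around the background (low
    concentration, so positions are conserved to varying degrees, like the
    columns of a real family alignment); a single global mixing weight
    toward the background is then tuned by bisection so the mean relative
    entropy matches ``entropy_target`` — the same one-scalar re-weighting
    that entropy-weighted model building applies to observed counts.
    """
    rng = np.random.default_rng(seed)
    strong = rng.dirichlet(0.2 * K * BACKGROUND, size=M)
    strong = np.maximum(strong, 1e-5)
    strong /= strong.sum(axis=1, keepdims=True)

    def mix(w: float) -> np.ndarray:
        e = w * strong + (1 - w) * BACKGROUND
        return e / e.sum(axis=1, keepdims=True)

    w = 1.0
    if entropy_target is not None:
        h = lambda w: float(np.mean(np.sum(
            mix(w) * np.log2(mix(w) / BACKGROUND), axis=1)))
        lo, hi = 0.0, 1.0
        for _ in range(60):
            w = 0.5 * (lo + hi)
            if h(w) > entropy_target:
                hi = w
            else:
                lo = w
    emis = mix(w)

    jitter = rng.uniform(0.9, 1.1, size=M)
    t_mi = 0.01 * jitter
    t_md = 0.01 * jitter
    t_mm = 1.0 - t_mi - t_md
    t_ii = np.full(M, 0.35)
    t_im = 1.0 - t_ii
    t_dd = np.full(M, 0.35)
    t_dm = 1.0 - t_dd
    return CoreProfile(name=name, match_emissions=emis,
                       t_mm=t_mm, t_mi=t_mi, t_md=t_md,
                       t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd)


def sample_from_profile(core: CoreProfile, n: int,
                        seed: int | np.random.Generator = 0) -> list[str]:
    """Ungapped consensus-length sequences sampled from match emissions."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols = np.stack([rng.choice(K, size=n, p=e)
                     for e in core.match_emissions])  # (M, n)
    return [AMINO.decode(cols[:, i]) for i in range(n)]


def synthetic_family_msa(M: int = 80, n_clusters: int = 3,
                         members: int = 4, divergence: float = 0.15,
                         seed: int = 0, name: str = "fam") -> MSA:
    """Ungapped family alignment with built-in identity cluster structure.

    Each cluster descends from its own random ancestor (clusters are
    unrelated, so cross-cluster identity sits at the ~6% random level);
    members diverge from the ancestor by point substitutions at the given
    rate, keeping within-cluster identity near 1 - divergence.
    """
    rng = np.random.default_rng(seed)
    ids, rows = [], []
    for c in range(n_clusters):
        anc = AMINO.encode(sample_iid(M, seed=rng))
        for m in range(members):
            row = anc.copy()
            nmut = rng.binomial(M, divergence)
            pos = rng.choice(M, size=nmut, replace=False)
            row[pos] = rng.integers(0, K, size=nmut)
            ids.append(f"{name}_c{c}_{m}")
            rows.append(AMINO.decode(row))
    return MSA(name=name, ids=ids, rows=rows)


def sample_db_length(rng: np.random.Generator,
                     lengths: list[int] | None = None) -> int:
    """Target-length draw: empirical db lengths or the log-normal surrogate."""
    if lengths:
        return int(lengths[rng.integers(0, len(lengths))])
    return max(1, int(round(LOGNORMAL_MEDIAN
                            * np.exp(rng.normal(0.0, LOGNORMAL_SIGMA)))))


# ---------------------------------------------------------------------------
# profmark benchmark construction
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkSet:
    queries: list[MSA]
    positives: list[SequenceRecord]
    decoys: list[SequenceRecord]
    #: target id -> {"query": name or "decoy", "domains": [(start, end)], ...}
    truth: dict[str, dict]
    params: dict = field(default_factory=dict)
    seed: int = 0
    n_skipped: int = 0

    @property
    def targets(self) -> list[tuple[str, str]]:
        return [(r.id, r.seq) for r in self.positives + self.decoys]


def _degap(row: str) -> str:
    return "".join(c for c in row if c not in "-.~")


def _nonhom_segment(length: int, negmode: str, seqdb: list[str],
                    rng: np.random.Generator) -> str:
    if length == 0:
        return ""
    if negmode == "iid" or not seqdb:
        return sample_iid(length, seed=rng)
    # pick a random db segment of the needed length, then shuffle/reverse it
    candidates = [s for s in seqdb if len(s) >= length]
    if not candidates:
        return sample_iid(length, seed=rng)
    src = candidates[rng.integers(0, len(candidates))]
    start = rng.integers(0, len(src) - length + 1)
    seg = src[start:start + length]
    if negmode == "mono":
        return shuffle_seq(seg, "mono", rng)
    if negmode == "di":
        return shuffle_seq(seg, "di", rng) if length >= 2 else seg
    if negmode == "reverse":
        return seg[::-1]
    raise ValueError(f"unknown negmode {negmode!r}")


def _compose(domains: list[str], total: int, negmode: str,
             seqdb: list[str], rng: np.random.Generator
             ) -> tuple[str, list[tuple[int, int]], list[int]]:
    """Embed domains (in order) at random positions in nonhomologous context.

    Returns (sequence, 1-based closed domain coordinates, all segment
    lengths in order: flank, dom, [flank, dom,] flank).
    """
    dom_total = sum(len(d) for d in domains)
    spare = total - dom_total
    nflank = len(domains) + 1
    # random composition of `spare` into nflank parts (stars and bars)
    if spare > 0:
        cuts = np.sort(rng.choice(spare + nflank - 1, size=nflank - 1,
                                  replace=False))
        parts = np.diff(np.concatenate([[-1], cuts, [spare + nflank - 1]])) - 1
    else:
        parts = np.zeros(nflank, dtype=int)
    pieces, coords, seglens = [], [], []
    pos = 0
    for i, d in enumerate(domains):
        flank = _nonhom_segment(int(parts[i]), negmode, seqdb, rng)
        pieces.append(flank)
        seglens.append(len(flank))
        pos += len(flank)
        coords.append((pos + 1, pos + len(d)))
        pieces.append(d)
        seglens.append(len(d))
        pos += len(d)
    flank = _nonhom_segment(int(parts[-1]), negmode, seqdb, rng)
    pieces.append(flank)
    seglens.append(len(flank))
    return "".join(pieces), coords, seglens


def profmark_build(msas: list[MSA], seqdb: list[str] | None,
                   frag_frac: float = 0.7, qthresh: float = 0.25,
                   tthresh: float = 0.5, ndomains: int = 1,
                   negmode: str = "mono", n_neg: int = 200,
                   seed: int = 0) -> BenchmarkSet:
    """Build a sensitivity/specificity benchmark from trusted alignments.

    Per alignment: map degeneracies to X; drop fragments (unaligned length
    < frag_frac * mean); single-linkage cluster at qthresh identity (skip
    if one cluster); the largest cluster becomes the query alignment;
    re-cluster the rest at tthresh (skip if fewer than two clusters) and
    draw one random *true test domain* per cluster.  Test domains are
    embedded (singly or in pairs) in nonhomologous context whose total
    length is drawn from the target database's length distribution,
    conditioned to fit the domains (rejection sampling).  Decoys copy the
    segment-length structure of randomly chosen positives.
    """
    if ndomains not in (1, 2):
        raise ValueError("ndomains must be 1 or 2")
    rng = np.random.default_rng(seed)
    db_lengths = [len(s) for s in seqdb] if seqdb else None

    queries: list[MSA] = []
    positives: list[SequenceRecord] = []
    truth: dict[str, dict] = {}
    pos_seglens: list[list[int]] = []
    n_skipped = 0
    domain_rows: dict[str, tuple[str, list[str]]] = {}  # for post-hoc checks

    for msa in msas:
        rows = [ "".join(c if c in "-.~" else AMINO.canonicalize(c)
                          for c in r) for r in msa.rows]
        ids = list(msa.ids)
        # fragment removal
        lens = np.array([len(_degap(r)) for r in rows], dtype=float)
        keep = lens >= frag_frac * lens.mean()
        rows = [r for r, k in zip(rows, keep) if k]
        ids = [i for i, k in zip(ids, keep) if k]
        if len(rows) < 2:
            n_skipped += 1
            continue
        ident = lambda i, j: percent_identity(rows[i], rows[j])
        clusters = single_linkage(len(rows), ident, qthresh)
        if len(clusters) < 2:
            n_skipped += 1
            continue
        qidx = clusters[0]
        rest = [i for c in clusters[1:] for i in c]
        tclusters = single_linkage(
            len(rest), lambda a, b: percent_identity(rows[rest[a]], rows[rest[b]]),
            tthresh)
        if len(tclusters) < 2:
            n_skipped += 1
            continue
        qname = msa.name
        queries.append(MSA(name=qname, ids=[ids[i] for i in qidx],
                           rows=[rows[i] for i in qidx]))
        test_rows = [rows[rest[c[rng.integers(0, len(c))]]] for c in tclusters]
        rng.shuffle(test_rows)

        # assemble test sequences with 1 or 2 embedded domains
        step = ndomains
        for t0 in range(0, len(test_rows) - step + 1, step):
            doms_aligned = test_rows[t0:t0 + step]
            doms = [_degap(r) for r in doms_aligned]
            need = sum(len(d) for d in doms)
            total = None
            for _ in range(10000):
                cand = sample_db_length(rng, db_lengths)
                if cand >= need:
                    total = cand
                    break
            if total is None:
                total = need + sample_db_length(rng, db_lengths)
            seq, coords, seglens = _compose(doms, total, negmode,
                                            seqdb or [], rng)
            tid = f"pos_{len(positives)}"
            positives.append(SequenceRecord(tid, seq))
            truth[tid] = {"query": qname, "domains": coords}
            pos_seglens.append(seglens)
            domain_rows[tid] = (qname, doms_aligned)

    if not positives:
        raise ValueError("no usable alignments: every input was skipped")

    decoys: list[SequenceRecord] = []
    for d in range(n_neg):
        seglens = pos_seglens[rng.integers(0, len(pos_seglens))]
        segs = [_nonhom_segment(sl, negmode, seqdb or [], rng)
                for sl in seglens]
        tid = f"decoy_{d}"
        decoys.append(SequenceRecord(tid, "".join(segs)))
        truth[tid] = {"query": "decoy", "domains": []}

    bench = BenchmarkSet(queries=queries, positives=positives, decoys=decoys,
                         truth=truth, seed=seed, n_skipped=n_skipped,
                         params=dict(frag_frac=frag_frac, qthresh=qthresh,
                                     tthresh=tthresh, ndomains=ndomains,
                                     negmode=negmode, n_neg=n_neg))
    _verify_benchmark(bench, domain_rows, qthresh, tthresh)
    return bench


def _verify_benchmark(bench: BenchmarkSet,
                      domain_rows: dict[str, tuple[str, list[str]]],
                      qthresh: float, tthresh: float) -> None:
    """Re-check the identity guarantees on the built benchmark."""
    qrows = {q.name: q.rows for q in bench.queries}
    by_query: dict[str, list[str]] = {}
    for tid, (qname, doms) in domain_rows.items():
        for dr in doms:
            for qr in qrows[qname]:
                if percent_identity(dr, qr) > qthresh:
                    raise AssertionError(
                        f"test domain in {tid} exceeds {qthresh:.0%} identity "
                        "to a query sequence")
            by_query.setdefault(qname, []).append(dr)
    for qname, doms in by_query.items():
        for i in range(len(doms)):
            for j in range(i + 1, len(doms)):
                if percent_identity(doms[i], doms[j]) > tthresh:
                    raise AssertionError(
                        f"two test domains of {qname} exceed "
                        f"{tthresh:.0%} identity")
    for rec in bench.positives:
        nd = len(bench.truth[rec.id]["domains"])
        if nd not in (1, 2):
            raise AssertionError("positive without 1 or 2 embedded domains")


# ---------------------------------------------------------------------------
# calibration / roundoff experiment drivers
# ---------------------------------------------------------------------------

def filter_fraction_experiment(sp: SearchProfile, cal: Calibration,
                               Pthr: float = 0.02, n: int = 50000,
                               L: int = 400, seed: int = 0,
                               rp=None, batch: int = 5000) -> float:
    """Observed fraction of i.i.d. null sequences passing the MSV filter.

    With accurate P-values the fraction should equal ``Pthr``.
    """
    from .msv import msv_filter_batch
    from .striped import reduce_profile

    if n < 100:
        raise ValueError("need at least 100 sequences")
    if rp is None:
        rp = reduce_profile(sp)
    rng = np.random.default_rng(seed)
    spL = sp.with_length(L)
    n_pass = 0
    done = 0
    while done < n:
        b = min(batch, n - done)
        X = sample_iid_batch(sp.null.freqs, b, L, rng)
        sc, over, _ = msv_filter_batch(rp, spL, X)
        p = gumbel_pvalue(sc, cal.msv)
        n_pass += int(np.sum((p < Pthr) | over))
        done += b
    return n_pass / n


def roundoff_experiment(sp: SearchProfile, rp, n: int = 1000, L: int = 400,
                        seed: int = 0, batch: int = 1000) -> dict[str, float]:
    """Distribution of (byte-filter MSV - float MSV) score differences."""
    from .msv import msv_filter_batch, msv_score_batch

    if n < 100:
        raise ValueError("need at least 100 sequences")
    rng = np.random.default_rng(seed)
    spL = sp.with_length(L)
    diffs = []
    done = 0
    while done < n:
        b = min(batch, n - done)
        X = sample_iid_batch(sp.null.freqs, b, L, rng)
        approx, _, _ = msv_filter_batch(rp, spL, X)
        exact = msv_score_batch(spL, X)
        diffs.append(approx - exact)
        done += b
    d = np.concatenate(diffs)
    return {"mean": float(d.mean()), "std": float(d.std()),
            "max_abs": float(np.abs(d).max())}


# ---------------------------------------------------------------------------
# ROC reporting
# ---------------------------------------------------------------------------

def roc_curve(ranked_ids: list[str], truth: dict[str, dict],
              ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (false positives, true-positive fraction) down a ranking."""
    n_pos = sum(1 for v in truth.values() if v["query"] != "decoy")
    fp, tp = 0, 0
    fps, tprs = [], []
    for tid in ranked_ids:
        if truth.get(tid, {}).get("query", "decoy") == "decoy":
            fp += 1
        else:
            tp += 1
        fps.append(fp)
        tprs.append(tp / max(1, n_pos))
    return np.asarray(fps), np.asarray(tprs)
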