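"""Readers and writers: FASTA, Stockholm / aligned FASTA, the tool's own
text profile format, and tabular search results.

Sequence and alignment parsing is delegated to Biopython (Bio.SeqIO /
Bio.AlignIO); records are canonicalized on input so that every residue is
one of the 20 amino acids or X (degenerate codes B/Z/J/U/O and unknowns map
to X, with a count kept on the record stream).

The profile format is a plain key-value/section text format holding the
model name, length, alphabet, background, per-position emissions and
transitions at full precision, and any calibration parameters.  Scores are
re-derived after loading, never re-quantized from stored integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .alphabet import AMINO, K
from .profile import CoreProfile
from .stats import Calibration

log = logging.getLogger("msvscan")

PROFILE_MAGIC = "msvscan-profile"
PROFILE_VERSION = "1"


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""


@dataclass
class MSA:
    """A multiple alignment: named rows of equal aligned length."""

    name: str
    ids: list[str]
    rows: list[str]
    reference_line: str | None = None  # Stockholm #=GC RF, if present

    def __post_init__(self) -> None:
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("ragged alignment")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file; residues are canonicalized (degenerates -> X)."""
    records = []
    n_degen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        n_degen += AMINO.count_degenerate(raw) - raw.upper().count("X")
        records.append(SequenceRecord(rec.id, AMINO.canonicalize(raw),
                                      rec.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_degen:
        log.info("mapped %d degenerate residues to X", n_degen)
    return records


def write_fasta(path, records: list[SequenceRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _norm_aligned(row: str) -> str:
    """Canonicalize residues, normalize gap characters to '-'."""
    out = []
    for c in row:
        if c in "-.~":
            out.append("-")
        else:
            out.append(AMINO.canonicalize(c))
    return "".join(out)


def read_msa(path, fmt: str = "stockholm", name: str | None = None) -> MSA:
    """Read one alignment in Stockholm or aligned-FASTA ('afa') format."""
    biofmt = {"stockholm": "stockholm", "afa": "fasta"}.get(fmt)
    if biofmt is None:
        raise ValueError("format must be 'stockholm' or 'afa'")
    aln = AlignIO.read(str(path), biofmt)
    ref = aln.column_annotations.get("reference_annotation") \
        if hasattr(aln, "column_annotations") else None
    return MSA(
        name=name or str(path),
        ids=[r.id for r in aln],
        rows=[_norm_aligned(str(r.seq)) for r in aln],
        reference_line=ref,
    )


def write_stockholm(path, msa: MSA) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(max(len(i) for i in msa.ids), len("#=GC RF")) + 2
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f"{sid:<{width}}{row}\n")
        if msa.reference_line is not None:
            fh.write(f"{'#=GC RF':<{width}}{msa.reference_line}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# profile text format
# ---------------------------------------------------------------------------

_T_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


def save_profile(path, core: CoreProfile, cal: Calibration | None = None) -> None:
    """Write a core profile (and optional calibration) at full precision."""
    with open(path, "w") as fh:
        fh.write(f"{PROFILE_MAGIC} {PROFILE_VERSION}\n")
        fh.write(f"name {core.name}\n")
        fh.write(f"alphabet {AMINO.symbols}\n")
        fh.write(f"M {core.M}\n")
        fh.write("background " + " ".join(f"{v:.17g}" for v in core.background) + "\n")
        if cal is not None:
            for k, v in cal.to_dict().items():
                fh.write(f"cal_{k} {v:.17g}\n")
        fh.write("emissions\n")
        for row in core.match_emissions:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
        fh.write("transitions\n")
        for j in range(core.M):
            vals = [getattr(core, "t_" + nm)[j] for nm in _T_NAMES]
            fh.write(" ".join(f"{v:.17g}" for v in vals) + "\n")
        fh.write("end\n")


def load_profile(path) -> tuple[CoreProfile, Calibration | None]:
    """Read a profile file back; inverse of :func:`save_profile`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    it = iter(lines)
    first = next(it, "")
    if not first.startswith(PROFILE_MAGIC):
        raise ValueError("not a msvscan profile file")
    if first.split()[1] != PROFILE_VERSION:
        raise ValueError(f"unsupported profile version: {first.split()[1]}")

    header: dict[str, str] = {}
    cal_d: dict[str, float] = {}
    line = next(it, None)
    while line is not None and line != "emissions":
        key, _, val = line.partition(" ")
        if key.startswith("cal_"):
            cal_d[key[4:]] = float(val)
        else:
            header[key] = val
        line = next(it, None)
    if line != "emissions":
        raise ValueError("truncated profile file: missing 'emissions' section")
    for req in ("name", "M", "background"):
        if req not in header:
            raise ValueError(f"truncated profile file: missing '{req}'")

    M = int(header["M"])
    emis = []
    for _ in range(M):
        row = next(it, None)
        if row is None:
            raise ValueError("truncated profile file: incomplete emissions")
        emis.append([float(v) for v in row.split()])
    if next(it, None) != "transitions":
        raise ValueError("truncated profile file: missing 'transitions' section")
    trans = []
    for _ in range(M):
        row = next(it, None)
        if row is None:
            raise ValueError("truncated profile file: incomplete transitions")
        trans.append([float(v) for v in row.split()])
    trans = np.array(trans)

    core = CoreProfile(
        name=header["name"],
        match_emissions=np.array(emis),
        background=np.array([float(v) for v in header["background"].split()]),
        **{"t_" + nm: trans[:, j] for j, nm in enumerate(_T_NAMES)},
    )
    cal = Calibration.from_dict(cal_d) if cal_d else None
    return core, cal


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def hits_to_frame(hits) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append({
            "target": h.target, "length": h.L, "stage": h.stage_reached,
            "msv_bits": h.msv_bits, "msv_p": h.msv_p, "bias_p": h.bias_p,
            "vit_bits": h.vit_bits, "vit_p": h.vit_p,
            "fwd_bits": h.fwd_bits, "fwd_p": h.fwd_p, "evalue": h.evalue,
        })
    return pd.DataFrame(rows)


def write_results(path, hits, stats=None, meta: dict | None = None) -> None:
    """TSV results: one row per reported hit, commented header and footer."""
    df = hits_to_frame([h for h in hits if h.stage_reached == "reported"])
    with open(path, "w") as fh:
        fh.write("# msvscan search results\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        cols = ["target", "length", "msv_bits", "vit_bits", "fwd_bits",
                "msv_p", "vit_p", "fwd_p", "evalue", "stage"]
        fh.write("\t".join(cols) + "\n")
        for _, r in df.iterrows():
            out = []
            for c in cols:
                v = r.get(c)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    out.append("-")
                elif c.endswith("_bits"):
                    out.append(f"{v:.1f}")
                elif c.endswith("_p") or c == "evalue":
                    out.append(f"{v:.2g}")
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")
        if stats is not None:
            for k, v in stats.as_dict().items():
                fh.write(f"# {k}: {v}\n")
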