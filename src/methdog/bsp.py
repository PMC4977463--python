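"""Bisulfite-sequencing-PCR (BSP) clone analysis.

Sanger reads of cloned bisulfite-PCR amplicons are aligned to the expected
fully-converted reference; each CpG cytosine is read as methylated (C),
unmethylated (T) or ambiguous.  Conversion efficiency is estimated from
non-CpG cytosines only — a conversion failure at a CpG is chemically
indistinguishable from methylation — and clones below the efficiency cutoff
(by default 95%, inclusive) are excluded before per-site methylation
fractions are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

__all__ = [
    "Amplicon",
    "CloneCall",
    "BSPMatrix",
    "convert_reference",
    "call_clone",
    "filter_clones",
    "site_fractions",
    "read_fasta",
]

METHYLATED = "M"
UNMETHYLATED = "U"
AMBIGUOUS = "?"


@dataclass(frozen=True)
class Amplicon:
    """A BSP amplicon reference (forward strand, unconverted)."""

    id: str
    seq: str
    cpg_positions: tuple[int, ...]
    non_cpg_c_positions: tuple[int, ...]

    @classmethod
    def from_sequence(cls, amplicon_id: str, seq: str) -> "Amplicon":
        seq = seq.upper()
        if set(seq) - set("ACGT"):
            raise ValueError("amplicon sequence must be A/C/G/T only")
        cpg = tuple(i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
        other_c = tuple(i for i, b in enumerate(seq) if b == "C" and i not in set(cpg))
        return cls(amplicon_id, seq, cpg, other_c)

    @property
    def n_sites(self) -> int:
        return len(self.cpg_positions)


@dataclass
class CloneCall:
    """Per-CpG methylation states of one sequenced bacterial clone."""

    clone_id: str
    states: tuple[str, ...]  # METHYLATED / UNMETHYLATED / AMBIGUOUS per CpG
    conversion_rate: float  # fraction of non-CpG Cs read as T
    n_informative: int  # non-CpG C positions aligned to a base
    identity: float
    reverse_complemented: bool = False


@dataclass
class BSPMatrix:
    """Clone-by-site state matrix plus per-site methylation fractions.

    Fractions count methylated over non-ambiguous calls; a site where every
    clone is ambiguous has a NaN fraction."""

    clone_ids: list[str]
    states: list[tuple[str, ...]]
    fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"cpg_{i + 1}" for i in range(len(self.fractions))]
        return pd.DataFrame([list(s) for s in self.states], index=self.clone_ids, columns=cols)


def convert_reference(amplicon: Amplicon) -> str:
    """Expected fully-converted template: non-CpG C -> T; CpG-site Cs become
    two-state positions (C if methylated, T if not), written as ``Y``."""
    cpg = set(amplicon.cpg_positions)
    out = []
    for i, base in enumerate(amplicon.seq):
        if i in cpg:
            out.append("Y")
        elif base == "C":
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def _aligner() -> Align.PairwiseAligner:
    # global alignment, match +1 / mismatch -1, linear gap -2; the template
    # letter Y (CpG cytosine) matches both C and T at full score
    alphabet = "ACGTYN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            mat[x, y] = 1.0 if x == y else -1.0
    for b in "CT":
        mat["Y", b] = mat[b, "Y"] = 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _aligner()


def _align(template: str, clone_seq: str):
    aln = _ALIGNER.align(template, clone_seq)[0]
    t_row, q_row = str(aln[0]), str(aln[1])
    matches = sum(
        1
        for t, q in zip(t_row, q_row)
        if t != "-" and q != "-" and (t == q or (t == "Y" and q in "CT"))
    )
    identity = matches / len(t_row)
    return t_row, q_row, identity, aln.score


def call_clone(clone_seq: str, amplicon: Amplicon, min_identity: float = 0.6,
               clone_id: str = "") -> CloneCall:
    """Call per-CpG states of one clone read against the converted template.

    Both orientations are tried and the higher-scoring alignment kept.  At
    each CpG column the aligned clone base gives the state (C methylated,
    T unmethylated, anything else ambiguous); the conversion rate is the
    fraction of non-CpG C template positions read as T among those aligned
    to a base.  Reads below ``min_identity`` are rejected."""
    clone_seq = clone_seq.upper()
    template = convert_reference(amplicon)
    fwd = _align(template, clone_seq)
    rev = _align(template, reverse_complement(clone_seq))
    (t_row, q_row, identity, _score), revcomp = (
        (fwd, False) if fwd[3] >= rev[3] else (rev, True)
    )
    if identity < min_identity:
        raise ValueError(
            f"clone {clone_id or '<unnamed>'}: alignment identity "
            f"{identity:.2f} below {min_identity:.2f}; not a read of this amplicon?"
        )
    # map template positions to aligned clone bases
    aligned_base: dict[int, str] = {}
    ti = 0
    for t, q in zip(t_row, q_row):
        if t != "-":
            aligned_base[ti] = q  # '-' recorded for deletions
            ti += 1
    states = []
    for p in amplicon.cpg_positions:
        b = aligned_base.get(p, "-")
        states.append(METHYLATED if b == "C" else UNMETHYLATED if b == "T" else AMBIGUOUS)
    informative = [
        aligned_base[p]
        for p in amplicon.non_cpg_c_positions
        if aligned_base.get(p, "-") in "ACGT"
    ]
    n_inf = len(informative)
    rate = sum(1 for b in informative if b == "T") / n_inf if n_inf else float("nan")
    return CloneCall(clone_id, tuple(states), rate, n_inf, identity, revcomp)


def filter_clones(calls: list[CloneCall], min_conversion: float = 0.95) -> list[CloneCall]:
    """Keep clones with conversion efficiency >= the cutoff (inclusive)."""
    return [c for c in calls if c.conversion_rate >= min_conversion]


def site_fractions(calls: list[CloneCall]) -> BSPMatrix:
    """Per-site methylated fraction over non-ambiguous calls."""
    if not calls:
        raise ValueError("no retained clones")
    n_sites = len(calls[0].states)
    if any(len(c.states) != n_sites for c in calls):
        raise ValueError("clone calls disagree on the number of CpG sites")
    fractions = np.full(n_sites, np.nan)
    for s in range(n_sites):
        m = sum(1 for c in calls if c.states[s] == METHYLATED)
        u = sum(1 for c in calls if c.states[s] == UNMETHYLATED)
        if m + u:
            fractions[s] = m / (m + u)
    return BSPMatrix([c.clone_id for c in calls], [c.states for c in calls], fractions)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
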