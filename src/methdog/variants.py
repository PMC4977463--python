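"""Heuristic triage of candidate donor-versus-clone variants.

Implements the rule set used to screen caller output for de novo somatic
mutations and loss of heterozygosity (LOH) in cloned animals: read-level
base-quality QC, donor/clone depth bounds, clone-side variant-frequency and
supporting-read rules, intersection of two independent callsets, and
subtraction of known germline sites and repeat-masked regions.  Variant
calling itself is out of scope; inputs are caller-agnostic TSV tables or a
minimal VCF dialect.

Threshold conventions are transcribed literally: "more than"/"larger than"
are strict inequalities, "at least"/">=" are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "ReadRecord",
    "CandidateVariant",
    "VariantFilterConfig",
    "read_passes_qc",
    "filter_fastq",
    "apply_variant_rules",
    "intersect_callsets",
    "subtract_known",
    "read_variant_tsv",
    "write_variant_tsv",
    "read_variant_vcf",
    "write_variant_vcf",
]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    identifier: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.identifier}: base/quality length mismatch")


@dataclass(frozen=True)
class CandidateVariant:
    """One candidate donor-vs-clone variant from an upstream caller."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vartype: str  # "SNV" | "indel"
    claimed_class: str  # "somatic" | "LOH"
    donor_depth: int
    clone_depth: int
    clone_alt_reads: int
    clone_var_freq: float
    caller: str = ""
    both_callers: bool = False

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.claimed_class)


@dataclass(frozen=True)
class VariantFilterConfig:
    """Depth/frequency/support thresholds of the heuristic rules."""

    min_depth: int = 5
    max_depth: int = 100
    somatic_min_freq: float = 0.2  # strict: freq must exceed it
    loh_high: float = 0.75  # strict: freq must exceed it ...
    loh_low: float = 0.25  # ... or fall below this
    min_support: int = 2  # inclusive

    def __post_init__(self) -> None:
        if not 0 < self.loh_low < self.loh_high < 1:
            raise ValueError("need 0 < loh_low < loh_high < 1")


def read_passes_qc(read: ReadRecord, min_q: int = 20,
                   max_lowq_frac: float = 0.5, max_n_frac: float = 0.1) -> bool:
    """Read-level QC: fail reads with more than 50% low-quality bases
    (Q < 20) or more than 10% N bases (both strict inequalities)."""
    n = len(read.bases)
    if n == 0:
        return False
    lowq = sum(1 for q in read.qualities if q < min_q)
    n_bases = sum(1 for b in read.bases.upper() if b == "N")
    return not (lowq / n > max_lowq_frac or n_bases / n > max_n_frac)


def filter_fastq(path, out_path=None) -> tuple[int, int]:
    """Apply read QC to a FASTQ file; optionally write passing reads.

    Returns (n_pass, n_total)."""
    from Bio import SeqIO

    n_pass = n_total = 0
    out = open(out_path, "w") if out_path else None
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n_total += 1
            read = ReadRecord(rec.id, str(rec.seq),
                              tuple(rec.letter_annotations["phred_quality"]))
            if read_passes_qc(read):
                n_pass += 1
                if out is not None:
                    SeqIO.write(rec, out, "fastq")
    finally:
        if out is not None:
            out.close()
    return n_pass, n_total


def first_failed_rule(v: CandidateVariant, config: VariantFilterConfig) -> str | None:
    """Name of the first rule a variant fails, or None if it survives."""
    if not (config.min_depth <= v.donor_depth <= config.max_depth):
        return "donor_depth"
    if not (config.min_depth <= v.clone_depth <= config.max_depth):
        return "clone_depth"
    if v.claimed_class == "somatic":
        if not v.clone_var_freq > config.somatic_min_freq:
            return "somatic_freq"
    elif v.claimed_class == "LOH":
        if not (v.clone_var_freq > config.loh_high or v.clone_var_freq < config.loh_low):
            return "loh_freq"
    else:
        return "unknown_class"
    if v.clone_alt_reads < config.min_support:
        return "support"
    return None


def apply_variant_rules(
    variants: list[CandidateVariant], config: VariantFilterConfig | None = None
) -> tuple[list[CandidateVariant], pd.DataFrame]:
    """Apply the depth/frequency/support rules.

    Returns the surviving variants (order preserved) and an audit table with
    one row per input variant recording the first failed rule (or "pass")."""
    config = config or VariantFilterConfig()
    kept, audit = [], []
    for v in variants:
        failed = first_failed_rule(v, config)
        if failed is None:
            kept.append(v)
        audit.append(
            dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                 claimed_class=v.claimed_class, caller=v.caller,
                 outcome="pass" if failed is None else failed)
        )
    return kept, pd.DataFrame(audit)


def intersect_callsets(
    a: list[CandidateVariant], b: list[CandidateVariant]
) -> list[CandidateVariant]:
    """Variants present in both callsets, keyed by
    (chrom, pos, ref, alt, class); the first set's records are kept and
    flagged as confirmed by both callers."""
    b_keys = {v.key for v in b}
    return [replace(v, both_callers=True) for v in a if v.key in b_keys]


def subtract_known(
    variants: list[CandidateVariant],
    known_sites: set[tuple[str, int]] | None = None,
    masked_regions: pd.DataFrame | None = None,
) -> list[CandidateVariant]:
    """Drop variants at known germline sites or inside masked (e.g. repeat)
    regions; masks are half-open BED intervals."""
    known_sites = known_sites or set()
    masks: dict[str, list[tuple[int, int]]] = {}
    if masked_regions is not None:
        for row in masked_regions.itertuples(index=False):
            masks.setdefault(row.chrom, []).append((row.start, row.end))
    out = []
    for v in variants:
        if (v.chrom, v.pos) in known_sites:
            continue
        if any(s <= v.pos < e for s, e in masks.get(v.chrom, [])):
            continue
        out.append(v)
    return out


VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vartype", "claimed_class",
    "donor_depth", "clone_depth", "clone_alt_reads", "clone_var_freq", "caller",
]


def read_variant_tsv(path) -> list[CandidateVariant]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateVariant(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            vartype=str(r.vartype), claimed_class=str(r.claimed_class),
            donor_depth=int(r.donor_depth), clone_depth=int(r.clone_depth),
            clone_alt_reads=int(r.clone_alt_reads),
            clone_var_freq=float(r.clone_var_freq),
            caller=str(getattr(r, "caller", "")),
        )
        for r in df.itertuples(index=False)
    ]


def write_variant_tsv(variants: list[CandidateVariant], path) -> None:
    df = pd.DataFrame([{c: getattr(v, c) for c in VARIANT_COLUMNS} for v in variants])
    df.to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DONOR_DP,Number=1,Type=Integer,Description="Donor depth">
##INFO=<ID=CLONE_DP,Number=1,Type=Integer,Description="Clone depth">
##INFO=<ID=CLONE_AD,Number=1,Type=Integer,Description="Clone variant-supporting reads">
##INFO=<ID=VF,Number=1,Type=Float,Description="Clone variant frequency">
##INFO=<ID=VT,Number=1,Type=String,Description="Variant type (SNV/indel)">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Claimed class (somatic/LOH)">
##INFO=<ID=CALLER,Number=1,Type=String,Description="Originating caller">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variant_vcf(variants: list[CandidateVariant], path) -> None:
    """Write the minimal VCF dialect (1-based POS; depths/frequency in INFO)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in variants:
            info = (
                f"DONOR_DP={v.donor_depth};CLONE_DP={v.clone_depth};"
                f"CLONE_AD={v.clone_alt_reads};VF={v.clone_var_freq:g};"
                f"VT={v.vartype};CLASS={v.claimed_class}"
            )
            if v.caller:
                info += f";CALLER={v.caller}"
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")


def read_variant_vcf(path) -> list[CandidateVariant]:
    """Read the minimal VCF dialect written by :func:`write_variant_vcf`."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        out.append(
            CandidateVariant(
                chrom=rec.CHROM, pos=rec.POS - 1, ref=rec.REF, alt=rec.ALT[0],
                vartype=str(rec.INFO.get("VT", "SNV")),
                claimed_class=str(rec.INFO.get("CLASS", "somatic")),
                donor_depth=int(rec.INFO.get("DONOR_DP", 0)),
                clone_depth=int(rec.INFO.get("CLONE_DP", 0)),
                clone_alt_reads=int(rec.INFO.get("CLONE_AD", 0)),
                clone_var_freq=float(rec.INFO.get("VF", 0.0)),
                caller=str(rec.INFO.get("CALLER", "")),
            )
        )
    return out
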