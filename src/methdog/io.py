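"""Per-CpG count tracks, region sets, gene tables and the base methylation level.

The unit of observation is a single CpG site carrying the number of
methylation-supportive (``meth``) and non-methylation-supportive (``unmeth``)
bisulfite reads.  Coordinates are 0-based half-open throughout; the
Bismark-coverage dialect (1-based inclusive) is converted at the boundary.
CpGs are keyed by the forward-strand C; merging of symmetric-strand counts is
assumed done upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["chrom", "pos", "meth", "unmeth"]

__all__ = [
    "MethylomeTrack",
    "PairedTrack",
    "GenomeAnnotation",
    "methylation_level",
    "read_cpg_table",
    "write_cpg_table",
    "join_tracks",
    "load_annotation",
    "fraction_as_percent",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def methylation_level(meth: int, unmeth: int) -> float:
    """Methylation level of one CpG: meth / (meth + unmeth).

    Raises
    ------
    ValueError
        If the total depth is zero (the level is undefined; callers must
        pre-filter uncovered sites) or a count is negative.
    """
    if meth < 0 or unmeth < 0:
        raise ValueError(f"negative count: meth={meth}, unmeth={unmeth}")
    depth = meth + unmeth
    if depth == 0:
        raise ValueError("methylation level undefined at zero depth")
    return meth / depth


def fraction_as_percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded as printed in summary tables (e.g. 10/44 -> 22.7)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, digits)


def _validate_sites(df: pd.DataFrame, context: str) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    if list(df.columns) != TRACK_COLUMNS:
        df = df[TRACK_COLUMNS]
    for col in ("pos", "meth", "unmeth"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    if (df[["meth", "unmeth"]].to_numpy() < 0).any():
        raise ValueError(f"{context}: negative counts")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"{context}: duplicate CpG position {row.chrom}:{row.pos}")
    return df


@dataclass
class MethylomeTrack:
    """One sample's per-CpG counts, sorted by (chrom, pos) with unique positions."""

    sample_id: str
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.sites = _validate_sites(self.sites, f"track {self.sample_id!r}")

    @classmethod
    def from_records(cls, sample_id: str, records) -> "MethylomeTrack":
        """Build from an iterable of (chrom, pos, meth, unmeth) tuples."""
        df = pd.DataFrame(list(records), columns=TRACK_COLUMNS)
        return cls(sample_id, df)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def with_levels(self) -> pd.DataFrame:
        """Copy of the site table with depth and level columns (NaN at depth 0)."""
        df = self.sites.copy()
        depth = df["meth"] + df["unmeth"]
        df["depth"] = depth
        with np.errstate(invalid="ignore"):
            df["level"] = np.where(depth > 0, df["meth"] / depth.replace(0, 1), np.nan)
        df.loc[depth == 0, "level"] = np.nan
        return df

    def by_chrom(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for chrom, grp in self.sites.groupby("chrom", sort=True):
            yield chrom, grp


@dataclass
class PairedTrack:
    """CpGs joined across a donor and its clone, depth-filtered in both."""

    donor_id: str
    clone_id: str
    min_depth: int
    sites: pd.DataFrame  # chrom,pos,donor_meth,donor_unmeth,clone_meth,clone_unmeth

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def read_cpg_table(
    path, dialect: str = "simple_tsv", sample_id: str | None = None
) -> MethylomeTrack:
    """Read a per-CpG count table.

    ``simple_tsv`` columns: chrom, pos (0-based), meth, unmeth.
    ``bismark_cov`` columns: chrom, start (1-based), end, percent, meth,
    unmeth; the start is converted to 0-based and the percent column is
    ignored (levels are always recomputed from counts).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if dialect not in ("simple_tsv", "bismark_cov"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "simple_tsv":
                    if len(fields) < 4:
                        raise ValueError("expected 4 columns")
                    chrom, pos, meth, unmeth = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
                else:
                    if len(fields) < 6:
                        raise ValueError("expected 6 columns")
                    chrom = fields[0]
                    pos = int(fields[1]) - 1  # 1-based inclusive -> 0-based
                    meth, unmeth = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
            rows.append((chrom, pos, meth, unmeth))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    try:
        return MethylomeTrack(sample_id, df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_cpg_table(track: MethylomeTrack, path, dialect: str = "simple_tsv") -> None:
    """Write a track; inverse of :func:`read_cpg_table` for each dialect."""
    df = track.sites
    with open(path, "w") as fh:
        if dialect == "simple_tsv":
            for row in df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.meth}\t{row.unmeth}\n")
        elif dialect == "bismark_cov":
            for row in df.itertuples(index=False):
                depth = row.meth + row.unmeth
                pct = 100.0 * row.meth / depth if depth else 0.0
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:g}\t{row.meth}\t{row.unmeth}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def join_tracks(a: MethylomeTrack, b: MethylomeTrack, min_depth: int = 4) -> PairedTrack:
    """Join two tracks on CpG position, keeping sites covered at
    ``depth >= min_depth`` in *both* samples.  An empty intersection is a
    valid (empty) result, not an error."""
    left = a.sites.rename(columns={"meth": "donor_meth", "unmeth": "donor_unmeth"})
    right = b.sites.rename(columns={"meth": "clone_meth", "unmeth": "clone_unmeth"})
    merged = left.merge(right, on=["chrom", "pos"], how="inner")
    keep = (merged["donor_meth"] + merged["donor_unmeth"] >= min_depth) & (
        merged["clone_meth"] + merged["clone_unmeth"] >= min_depth
    )
    merged = merged[keep].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return PairedTrack(a.sample_id, b.sample_id, min_depth, merged)


GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]


@dataclass
class GenomeAnnotation:
    """Gene models plus named region sets (CGIs, repeats, masks, ...).

    Genes use 0-based half-open intervals with mandatory strand; the TSS of a
    minus-strand gene is its ``end`` coordinate.  Region sets whose
    chromosomes never occur in a track simply never match (a warning is
    logged at load time, not an error).
    """

    genes: pd.DataFrame
    region_sets: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        if list(g.columns) != GENE_COLUMNS:
            g = g[GENE_COLUMNS]
        bad_strand = ~g["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError(f"gene {g.loc[bad_strand.idxmax(), 'gene_id']!r}: strand must be + or -")
        if (g["start"] >= g["end"]).any():
            raise ValueError("gene with start >= end")
        self.genes = g
        for name, regions in self.region_sets.items():
            r = regions.reset_index(drop=True)[["chrom", "start", "end"]]
            if (r["start"] >= r["end"]).any():
                raise ValueError(f"region set {name!r}: interval with start >= end")
            self.region_sets[name] = r.sort_values(["chrom", "start"]).reset_index(drop=True)

    def tss(self) -> pd.Series:
        """Strand-aware TSS per gene (start on +, end on -)."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"]), index=g.index
        )


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file into a (chrom, start, end) frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED line") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: interval start >= end")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _read_gene_table(path) -> pd.DataFrame:
    """Gene table: headerless 5-column TSV (id, chrom, strand, start, end) or
    GFF-lite (9 columns, 1-based inclusive coords, ID=/gene_id attribute)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 9:  # GFF-lite
                    chrom, _src, _type, start, end, _score, strand, _frame, attrs = fields[:9]
                    gene_id = None
                    for token in attrs.replace("; ", ";").split(";"):
                        token = token.strip()
                        if token.startswith("ID="):
                            gene_id = token[3:]
                        elif token.startswith("gene_id"):
                            gene_id = token.split(None, 1)[1].strip('" ') if " " in token else token.split("=", 1)[1]
                    if gene_id is None:
                        raise ValueError("no ID=/gene_id attribute")
                    rows.append((gene_id, chrom, strand, int(start) - 1, int(end)))
                elif len(fields) == 5:
                    gene_id, chrom, strand, start, end = fields
                    rows.append((gene_id, chrom, strand, int(start), int(end)))
                else:
                    raise ValueError("expected 5 (TSV) or 9 (GFF) columns")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed gene line ({exc})") from exc
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def load_annotation(gene_path, region_paths: Mapping[str, object] | None = None) -> GenomeAnnotation:
    """Load gene models plus named BED region sets into one annotation."""
    genes = _read_gene_table(gene_path)
    region_sets = {name: read_bed(p) for name, p in (region_paths or {}).items()}
    ann = GenomeAnnotation(genes, region_sets)
    known = set(ann.genes["chrom"])
    for name, regions in ann.region_sets.items():
        unknown = set(regions["chrom"]) - known
        if known and unknown:
            logger.warning("region set %r has chromosomes absent from genes: %s", name, sorted(unknown))
    return ann
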