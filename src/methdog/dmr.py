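"""Sliding-window DMR identification between one donor and one clone methylome.

The algorithm scans each chromosome left to right over the depth-filtered
paired CpG sites:

1. *Seed*: a site with two-sided Fisher p <= ``p_site`` and absolute
   level difference >= ``min_site_diff`` starts a candidate region.
2. *Extension*: downstream sites are appended while the gap to the previous
   accepted site is <= ``max_gap`` and the span stays <= ``max_len``.
   A significant site must share the seed's tendency; a single
   non-significant site of opposite tendency is tolerated, but two
   consecutive opposite-tendency sites — or one *significant* opposite
   site — terminate the run.
3. *Trimming*: trailing non-significant sites are removed so the region
   ends on a significant CpG (the seed itself is never removed).
4. *Final filters*: regions must have >= ``min_sites`` CpGs, pooled
   |level difference| >= ``min_region_diff`` and length >= ``min_len``.

Emitted DMRs are non-overlapping; scanning resumes after each one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .io import GenomeAnnotation, PairedTrack

__all__ = [
    "DMRConfig",
    "PairedSite",
    "DMR",
    "fisher_exact_two_sided",
    "compare_sites",
    "is_seed",
    "extend_run",
    "trim_run",
    "region_levels",
    "call_dmrs",
    "annotate_dmrs",
    "recurrent_genes",
    "implant_sensitivity",
    "dmrs_to_frame",
]

# relative tie tolerance for the total-probability two-sided p, as used by
# standard Fisher implementations: tables whose hypergeometric probability is
# within (1 + EPS) of the observed table's count as "at most as probable".
_TIE_EPS = 1e-7


@dataclass(frozen=True)
class DMRConfig:
    """Thresholds of the sliding-window caller (defaults as used genome-wide).

    min_depth        minimum read depth per sample at a usable CpG
    p_site           per-site two-sided Fisher significance cutoff
    min_site_diff    minimum |level difference| for a seed CpG
    max_gap          maximum distance (bp) between adjacent member CpGs
    max_len          maximum DMR span (bp); reaching it terminates extension
    min_sites        minimum member CpGs in an emitted DMR
    min_region_diff  minimum pooled |level difference| of an emitted DMR
    min_len          minimum DMR span (bp)
    """

    min_depth: int = 4
    p_site: float = 0.01
    min_site_diff: float = 0.2
    max_gap: int = 200
    max_len: int = 2000
    min_sites: int = 5
    min_region_diff: float = 0.2
    min_len: int = 200

    def __post_init__(self) -> None:
        for name in ("min_depth", "p_site", "min_site_diff", "max_gap",
                     "max_len", "min_sites", "min_region_diff", "min_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


@dataclass(frozen=True)
class PairedSite:
    """One CpG joined across donor and clone with its per-site statistics.

    ``diff`` is clone level minus donor level; ``tendency`` is its sign
    (+1 clone hypermethylated, -1 hypomethylated, 0 equal)."""

    chrom: str
    pos: int
    donor_meth: int
    donor_unmeth: int
    clone_meth: int
    clone_unmeth: int
    donor_level: float
    clone_level: float
    diff: float
    tendency: int
    p: float


@dataclass
class DMR:
    """A called differentially methylated region (clone relative to donor)."""

    chrom: str
    start: int  # position of the first member CpG
    end: int  # position of the last member CpG + 1 (half-open)
    sites: list[PairedSite]
    n_cpg: int
    length: int  # last member pos - first member pos + 1
    donor_region_level: float
    clone_region_level: float
    region_diff: float
    direction: str  # "hyper" | "hypo"
    genes: list[str] = field(default_factory=list)
    promoter_genes: list[str] = field(default_factory=list)


@lru_cache(maxsize=1 << 20)
def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Total-probability method: the sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (within relative tolerance 1e-7).  A degenerate margin
    (any row or column summing to zero) gives p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    n = r1 + r2
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    p = pmf[pmf <= pmf[a - kmin] * (1 + _TIE_EPS)].sum()
    return float(min(1.0, p))


def compare_sites(paired: PairedTrack, config: DMRConfig | None = None) -> list[PairedSite]:
    """Annotate every paired CpG with levels, difference, tendency and
    Fisher p, preserving genomic order."""
    del config  # thresholds are applied downstream; kept for interface parity
    out: list[PairedSite] = []
    for row in paired.sites.itertuples(index=False):
        dm, du, cm, cu = int(row.donor_meth), int(row.donor_unmeth), int(row.clone_meth), int(row.clone_unmeth)
        donor_level = dm / (dm + du)
        clone_level = cm / (cm + cu)
        diff = clone_level - donor_level
        out.append(
            PairedSite(
                chrom=row.chrom,
                pos=int(row.pos),
                donor_meth=dm,
                donor_unmeth=du,
                clone_meth=cm,
                clone_unmeth=cu,
                donor_level=donor_level,
                clone_level=clone_level,
                diff=diff,
                tendency=int(np.sign(diff)),
                p=fisher_exact_two_sided(dm, du, cm, cu),
            )
        )
    return out


def is_seed(site: PairedSite, config: DMRConfig) -> bool:
    """A DMR start site: individually significant with a sizeable difference."""
    return site.p <= config.p_site and abs(site.diff) >= config.min_site_diff


def _opposite(site: PairedSite, seed_tendency: int) -> bool:
    # tendency 0 (equal levels) is neutral, never opposite
    return site.tendency != 0 and site.tendency == -seed_tendency


def extend_run(sites: list[PairedSite], seed_index: int, config: DMRConfig) -> range:
    """Extend downstream from a seed; returns the accepted contiguous index range.

    Acceptance of the next downstream site requires gap <= ``max_gap`` to the
    previously accepted site and span <= ``max_len`` from the seed, plus:
    significant sites must match the seed's tendency (a significant opposite
    site terminates the run); non-significant sites of any tendency are
    accepted unless this would make two consecutive opposite-tendency sites.
    """
    seed = sites[seed_index]
    if not is_seed(seed, config):
        raise ValueError("extend_run requires a valid seed site")
    seed_t = seed.tendency
    last = seed_index
    prev_opposite = False
    for j in range(seed_index + 1, len(sites)):
        nxt = sites[j]
        if nxt.chrom != seed.chrom:
            break
        if nxt.pos - sites[last].pos > config.max_gap:
            break
        if nxt.pos - seed.pos + 1 > config.max_len:
            break
        significant = nxt.p <= config.p_site
        opposite = _opposite(nxt, seed_t)
        if significant:
            if opposite:
                break
        else:
            if opposite and prev_opposite:
                break
        last = j
        prev_opposite = opposite
    return range(seed_index, last + 1)


def trim_run(sites: list[PairedSite], run: range, config: DMRConfig) -> range:
    """Drop trailing non-significant sites so the run ends on a significant
    CpG; the seed (first index) is never removed."""
    last = run.stop - 1
    while last > run.start and sites[last].p > config.p_site:
        last -= 1
    return range(run.start, last + 1)


def region_levels(run_sites: list[PairedSite]) -> tuple[float, float, float]:
    """Pooled (depth-weighted) levels of a site run and their difference."""
    if not run_sites:
        raise ValueError("empty run")
    dm = sum(s.donor_meth for s in run_sites)
    dt = sum(s.donor_meth + s.donor_unmeth for s in run_sites)
    cm = sum(s.clone_meth for s in run_sites)
    ct = sum(s.clone_meth + s.clone_unmeth for s in run_sites)
    donor = dm / dt
    clone = cm / ct
    return donor, clone, clone - donor


def _sites_table(sites: list[PairedSite]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in sites])
    if len(df):
        # BH-adjusted p is informational only; the caller uses the fixed
        # per-site cutoff without multiplicity correction
        df["p_bh"] = false_discovery_control(df["p"], method="bh")
    return df


def call_dmrs(
    paired: PairedTrack | list[PairedSite], config: DMRConfig | None = None
) -> tuple[list[DMR], pd.DataFrame]:
    """Run the full sliding-window scan.

    Returns the sorted, non-overlapping DMR list and the per-site statistics
    table (counts, levels, difference, Fisher p, BH-adjusted p).
    """
    config = config or DMRConfig()
    if isinstance(paired, PairedTrack):
        sites = compare_sites(paired, config)
    else:
        sites = list(paired)
    dmrs: list[DMR] = []
    # group indices per chromosome (input is sorted)
    start = 0
    for end in range(1, len(sites) + 1):
        if end == len(sites) or sites[end].chrom != sites[start].chrom:
            dmrs.extend(_scan_chrom(sites, start, end, config))
            start = end
    return dmrs, _sites_table(sites)


def _scan_chrom(sites: list[PairedSite], lo: int, hi: int, config: DMRConfig) -> list[DMR]:
    out: list[DMR] = []
    i = lo
    while i < hi:
        if not is_seed(sites[i], config):
            i += 1
            continue
        run = extend_run(sites, i, config)
        run = trim_run(sites, run, config)
        members = sites[run.start : run.stop]
        first, last = members[0], members[-1]
        length = last.pos - first.pos + 1
        donor, clone, diff = region_levels(members)
        if (
            len(members) >= config.min_sites
            and abs(diff) >= config.min_region_diff
            and length >= config.min_len
        ):
            out.append(
                DMR(
                    chrom=first.chrom,
                    start=first.pos,
                    end=last.pos + 1,
                    sites=members,
                    n_cpg=len(members),
                    length=length,
                    donor_region_level=donor,
                    clone_region_level=clone,
                    region_diff=diff,
                    direction="hyper" if diff > 0 else "hypo",
                )
            )
            i = run.stop  # resume after the emitted DMR
        else:
            i += 1
    return out


def _promoter_interval(strand: str, start: int, end: int, upstream: int, downstream: int) -> tuple[int, int]:
    if strand == "+":
        return max(0, start - upstream), start + downstream
    return max(0, end - downstream), end + upstream


def annotate_dmrs(
    dmrs: list[DMR],
    ann: GenomeAnnotation,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 0,
) -> list[DMR]:
    """Label each DMR with overlapping genes and promoter-overlapping genes.

    Promoters are strand-aware intervals around the TSS (by default 2 kb
    upstream, nothing downstream); any 1-bp overlap counts.  Returns new DMR
    objects; the input list is not modified.
    """
    genes_by_chrom: dict[str, list[tuple[str, str, int, int]]] = {}
    for g in ann.genes.itertuples(index=False):
        genes_by_chrom.setdefault(g.chrom, []).append((g.gene_id, g.strand, int(g.start), int(g.end)))
    out = []
    for d in dmrs:
        hits, prom_hits = [], []
        for gene_id, strand, gstart, gend in genes_by_chrom.get(d.chrom, []):
            if d.start < gend and gstart < d.end:
                hits.append(gene_id)
            pstart, pend = _promoter_interval(strand, gstart, gend, promoter_upstream, promoter_downstream)
            if pstart < pend and d.start < pend and pstart < d.end:
                prom_hits.append(gene_id)
        out.append(replace(d, genes=hits, promoter_genes=prom_hits))
    return out


def recurrent_genes(per_pair_gene_sets: list[set], min_pairs: int = 2) -> pd.DataFrame:
    """Count in how many donor-clone pairs each gene carries a DMR.

    Returns a frame (gene, n_pairs, recurrent) sorted by descending count;
    ``recurrent`` flags genes hit in at least ``min_pairs`` pairs.
    """
    counts: dict[str, int] = {}
    for s in per_pair_gene_sets:
        for gene in set(s):
            counts[gene] = counts.get(gene, 0) + 1
    df = pd.DataFrame(sorted(counts.items()), columns=["gene", "n_pairs"])
    df = df.sort_values(["n_pairs", "gene"], ascending=[False, True]).reset_index(drop=True)
    df["recurrent"] = df["n_pairs"] >= min_pairs
    return df


def implant_sensitivity(truth_bed: pd.DataFrame, dmrs: list[DMR], min_frac: float = 0.5) -> float:
    """Fraction of truth intervals recovered by a called DMR at the given
    reciprocal-overlap fraction (intersection >= ``min_frac`` of both)."""
    if len(truth_bed) == 0:
        raise ValueError("empty truth set")
    hit = 0
    for t in truth_bed.itertuples(index=False):
        tlen = t.end - t.start
        for d in dmrs:
            if d.chrom != t.chrom:
                continue
            inter = min(d.end, t.end) - max(d.start, t.start)
            if inter >= min_frac * tlen and inter >= min_frac * d.length:
                hit += 1
                break
    return hit / len(truth_bed)


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6+-style table of called DMRs (half-open intervals)."""
    rows = []
    for i, d in enumerate(dmrs, start=1):
        rows.append(
            dict(
                chrom=d.chrom,
                start=d.start,
                end=d.end,
                name=f"dmr_{i}",
                region_diff=d.region_diff,
                direction=d.direction,
                n_cpg=d.n_cpg,
                donor_level=d.donor_region_level,
                clone_level=d.clone_region_level,
                genes=",".join(d.genes),
                promoter_genes=",".join(d.promoter_genes),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "region_diff", "direction",
                 "n_cpg", "donor_level", "clone_level", "genes", "promoter_genes"],
    )
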