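"""Genome-wide methylome summaries: element-level pooled methylation, the
strand-oriented genic (metagene) profile, and bootstrap hierarchical
clustering of samples on per-CpG levels.

All regional summaries use pooled (depth-weighted) levels,
sum(meth)/sum(meth+unmeth), never the mean of per-site levels — robust to
depth variation and invariant to splitting a region into adjacent pieces.
Clustering uses 1 - Pearson correlation with average linkage, and ordinary
bootstrap probabilities over CpG sites for branch support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import squareform

from .io import GenomeAnnotation, MethylomeTrack

logger = logging.getLogger(__name__)

__all__ = [
    "ElementSummary",
    "GenicProfile",
    "Dendrogram",
    "merge_intervals",
    "cgi_shores",
    "element_mean_level",
    "genic_profile",
    "sample_distance_matrix",
    "hierarchical_cluster",
    "bootstrap_support",
]


@dataclass
class ElementSummary:
    """Pooled methylation of one sample over one named genomic element class."""

    element_name: str
    sample_id: str
    level: float  # NaN when no covered CpG falls in the element
    n_cpg: int
    depth: int


@dataclass
class GenicProfile:
    """Pooled methylation in ordered bins around and across gene bodies.

    Bins run 5'->3' in gene orientation: ``n_flank_bins`` fixed-width
    upstream bins, ``n_body_bins`` length-scaled body bins, then
    ``n_flank_bins`` downstream bins.  ``levels`` is NaN where no CpG fell
    in a bin."""

    sample_id: str
    n_flank_bins: int
    n_body_bins: int
    meth: np.ndarray
    total: np.ndarray
    n_genes: int

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    @property
    def levels(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        nf, nb = self.n_flank_bins, self.n_body_bins
        zone = ["upstream"] * nf + ["body"] * nb + ["downstream"] * nf
        return pd.DataFrame(
            {"bin": np.arange(self.n_bins), "zone": zone,
             "meth": self.meth, "total": self.total, "level": self.levels}
        )


def merge_intervals(regions: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping (chrom, start, end) intervals."""
    out = []
    for chrom, grp in regions.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = row.start, row.end
            elif row.start <= cur_e:
                cur_e = max(cur_e, row.end)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = row.start, row.end
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def cgi_shores(cgis: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """CGI shores: +-``flank`` bp around each CpG island, minus the islands
    themselves (the conventional definition; derived on demand)."""
    merged = merge_intervals(cgis)
    flanks = pd.DataFrame(
        [(r.chrom, max(0, r.start - flank), r.start) for r in merged.itertuples(index=False)]
        + [(r.chrom, r.end, r.end + flank) for r in merged.itertuples(index=False)],
        columns=["chrom", "start", "end"],
    )
    flanks = flanks[flanks["start"] < flanks["end"]]
    merged_flanks = merge_intervals(flanks)
    # subtract islands from the flank union
    out = []
    for chrom, grp in merged_flanks.groupby("chrom", sort=True):
        islands = merged[merged["chrom"] == chrom]
        cuts = list(zip(islands["start"], islands["end"]))
        for row in grp.itertuples(index=False):
            pieces = [(row.start, row.end)]
            for cs, ce in cuts:
                pieces = [
                    piece
                    for s, e in pieces
                    for piece in ((s, min(e, cs)), (max(s, ce), e))
                    if piece[0] < piece[1]
                ]
            out.extend((chrom, s, e) for s, e in pieces)
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _in_regions_mask(sites: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask over track rows: CpG inside the union of regions."""
    merged = merge_intervals(regions)
    mask = np.zeros(len(sites), dtype=bool)
    for chrom, grp in merged.groupby("chrom", sort=False):
        sel = sites["chrom"] == chrom
        if not sel.any():
            continue
        pos = sites.loc[sel, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        mask[np.flatnonzero(sel.to_numpy())] = inside
    return mask


def element_mean_level(
    track: MethylomeTrack, regions: pd.DataFrame, element_name: str = ""
) -> ElementSummary:
    """Pooled methylation over all CpGs inside a region set.

    Each CpG contributes once even when regions overlap.  With no covered
    CpG the summary carries n_cpg = 0 and a NaN level."""
    if len(regions) == 0:
        return ElementSummary(element_name, track.sample_id, float("nan"), 0, 0)
    mask = _in_regions_mask(track.sites, regions)
    sub = track.sites[mask]
    covered = sub[(sub["meth"] + sub["unmeth"]) > 0]
    depth = int((covered["meth"] + covered["unmeth"]).sum())
    if depth == 0:
        return ElementSummary(element_name, track.sample_id, float("nan"), 0, 0)
    level = float(covered["meth"].sum() / depth)
    return ElementSummary(element_name, track.sample_id, level, len(covered), depth)


def genic_profile(
    track: MethylomeTrack,
    genes: pd.DataFrame | GenomeAnnotation,
    flank: int = 2000,
    bin_size: int = 100,
    n_body_bins: int = 20,
) -> GenicProfile:
    """Metagene methylation profile: fixed-width flank bins plus
    length-scaled gene-body bins, aggregated over genes by pooled counts.

    Minus-strand genes are flipped so bin 0 is always the most-upstream
    flank bin.  Genes shorter than ``n_body_bins`` bases are skipped."""
    if isinstance(genes, GenomeAnnotation):
        genes = genes.genes
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    nf = flank // bin_size
    n_bins = 2 * nf + n_body_bins
    meth = np.zeros(n_bins, dtype=np.int64)
    total = np.zeros(n_bins, dtype=np.int64)
    n_used = 0
    sites = track.sites
    for g in genes.itertuples(index=False):
        glen = g.end - g.start
        if glen < n_body_bins:
            logger.warning("gene %s shorter than n_body_bins; skipped", g.gene_id)
            continue
        n_used += 1
        sel = (
            (sites["chrom"] == g.chrom)
            & (sites["pos"] >= g.start - flank)
            & (sites["pos"] < g.end + flank)
        )
        for row in sites[sel].itertuples(index=False):
            pos = row.pos
            if pos < g.start:  # left flank
                d = g.start - 1 - pos  # distance to the gene's left edge
                b = nf - 1 - d // bin_size if g.strand == "+" else 2 * nf + n_body_bins - 1 - d // bin_size
            elif pos >= g.end:  # right flank
                d = pos - g.end
                b = nf + n_body_bins + d // bin_size if g.strand == "+" else nf - 1 - d // bin_size
            else:  # body, length-scaled
                frac_bin = int((pos - g.start) * n_body_bins // glen)
                b = nf + (frac_bin if g.strand == "+" else n_body_bins - 1 - frac_bin)
            meth[b] += row.meth
            total[b] += row.meth + row.unmeth
    return GenicProfile(track.sample_id, nf, n_body_bins, meth, total, n_used)


def _level_matrix(tracks: list[MethylomeTrack], min_depth: int) -> tuple[list[str], np.ndarray]:
    """Per-CpG level matrix (samples x sites) over CpGs covered at
    >= min_depth in every sample."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    frames = []
    for i, t in enumerate(tracks):
        df = t.sites.copy()
        depth = df["meth"] + df["unmeth"]
        df = df[depth >= min_depth]
        df = df.assign(**{f"level_{i}": df["meth"] / (df["meth"] + df["unmeth"])})
        frames.append(df[["chrom", "pos", f"level_{i}"]])
    joined = reduce(lambda a, b: a.merge(b, on=["chrom", "pos"], how="inner"), frames)
    if len(joined) < 2:
        raise ValueError("fewer than 2 CpGs shared at the required depth")
    mat = joined[[f"level_{i}" for i in range(len(tracks))]].to_numpy().T
    return [t.sample_id for t in tracks], mat


def sample_distance_matrix(
    tracks: list[MethylomeTrack], min_depth: int = 4
) -> tuple[list[str], np.ndarray]:
    """Pairwise sample dissimilarity, 1 - Pearson correlation of per-CpG
    levels over CpGs covered in all samples."""
    ids, mat = _level_matrix(tracks, min_depth)
    return ids, _corr_distance(mat)


def _corr_distance(mat: np.ndarray) -> np.ndarray:
    d = 1.0 - np.corrcoef(mat)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry


@dataclass
class Dendrogram:
    """Average-linkage merge tree over samples with cophenetic heights and
    (optionally) bootstrap support per internal node."""

    labels: list[str]
    merge: np.ndarray  # scipy linkage matrix
    support: dict[frozenset, float] | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.merge[:, 2]

    def bipartitions(self) -> list[frozenset]:
        """Leaf-label set under each internal node, in merge order."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for i, (a, b, _h, _c) in enumerate(self.merge):
            members[n + i] = members[int(a)] | members[int(b)]
            out.append(members[n + i])
        return out

    def newick(self) -> str:
        """Newick export; internal node labels carry bootstrap support."""
        tree = to_tree(self.merge)
        sup = self.support or {}
        leafset = {i: frozenset([self.labels[i]]) for i in range(len(self.labels))}

        def clade(node) -> frozenset:
            if node.is_leaf():
                return leafset[node.id]
            return clade(node.left) | clade(node.right)

        def render(node, parent_height) -> str:
            blen = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{blen:.6g}"
            inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
            label = sup.get(clade(node))
            tag = f"{label:.2f}" if label is not None else ""
            return f"({inner}){tag}:{blen:.6g}"

        root = render(tree, tree.dist)
        return root.rsplit(":", 1)[0] + ";"


def hierarchical_cluster(
    dist: np.ndarray, labels: list[str] | None = None, method: str = "average"
) -> Dendrogram:
    """Agglomerate samples from a symmetric dissimilarity matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = [f"s{i}" for i in range(dist.shape[0])]
    condensed = squareform(dist, checks=False)
    merge = scipy_linkage(condensed, method=method)
    return Dendrogram(list(labels), merge)


def bootstrap_support(
    tracks: list[MethylomeTrack],
    B: int = 100,
    seed: int = 0,
    min_depth: int = 4,
    method: str = "average",
) -> Dendrogram:
    """Ordinary bootstrap probabilities for the sample dendrogram.

    CpG sites are resampled with replacement ``B`` times; the support of an
    internal node is the fraction of replicate dendrograms containing the
    identical leaf-set bipartition.  Reproducible for a fixed seed."""
    if B < 1:
        raise ValueError("B must be >= 1")
    ids, mat = _level_matrix(tracks, min_depth)
    base = hierarchical_cluster(_corr_distance(mat), ids, method=method)
    target = base.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_sites = mat.shape[1]
    for _ in range(B):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep = hierarchical_cluster(_corr_distance(mat[:, idx]), ids, method=method)
        seen = set(rep.bipartitions())
        for bp in target:
            if bp in seen:
                counts[bp] += 1
    base.support = {bp: c / B for bp, c in counts.items()}
    return base
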