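"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes:
clustered CpG positions (dense CpG islands on a sparser background),
bimodal beta-distributed true methylation levels (CGIs low, elsewhere
high), binomial read counts at truncated-Poisson depth, implanted DMRs of
chosen width and effect, null replicate pairs, bisulfite clone sequences
with imperfect conversion, and boundary-stratified candidate-variant
tables with independently enumerated expected survivors.

All randomness flows from one master seed through named substreams, so
adding a generator never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsp import Amplicon
from .io import GENE_COLUMNS, MethylomeTrack
from .variants import CandidateVariant, VariantFilterConfig

__all__ = [
    "SimGenome",
    "DMRSpec",
    "TruthSet",
    "substream",
    "simulate_genome",
    "simulate_pair",
    "simulate_null_pair",
    "simulate_three_pairs",
    "place_dmr_specs",
    "demo_amplicon",
    "simulate_bsp_clones",
    "simulate_variant_table",
]

# bimodal level model: Beta(1, 9) inside CGIs (mostly unmethylated),
# Beta(9, 1) elsewhere (mostly methylated)
DEFAULT_LEVEL_MODEL = (1.0, 9.0, 9.0, 1.0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG derived from (master seed, stream name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass
class SimGenome:
    """A toy genome: CpG coordinates, CGI intervals and gene models."""

    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    in_cgi: dict[str, np.ndarray]  # boolean per CpG
    cgis: pd.DataFrame
    genes: pd.DataFrame

    @property
    def n_cpg(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())


@dataclass(frozen=True)
class DMRSpec:
    """An implanted DMR: a run of consecutive CpGs shifted by ``delta``."""

    chrom: str
    start_index: int  # first CpG index on the chromosome
    end_index: int  # one past the last CpG index
    delta: float

    def __post_init__(self) -> None:
        if abs(self.delta) > 1:
            raise ValueError("|delta| must be <= 1")
        if self.end_index <= self.start_index:
            raise ValueError("empty CpG index range")


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated data."""

    dmr_bed: pd.DataFrame  # chrom, start, end, delta (half-open)
    donor_levels: dict[str, np.ndarray] = field(default_factory=dict)
    clone_levels: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 300_000,
    cgi_density: float = 1 / 30_000,
    background_spacing: int = 100,
    cgi_spacing: tuple[int, int] = (8, 20),
    cgi_length: tuple[int, int] = (500, 1500),
    gene_density: float = 1 / 25_000,
    gene_length: tuple[int, int] = (2_000, 8_000),
) -> SimGenome:
    """Draw a clustered-CpG toy genome.

    Background CpGs are spaced uniformly in [0.8, 1.2] x
    ``background_spacing``; CGIs carry dense CpGs at ``cgi_spacing``."""
    if min(n_chrom, chrom_len, background_spacing) <= 0:
        raise ValueError("parameters must be positive")
    if cgi_density > 0 and chrom_len < cgi_length[1]:
        raise ValueError("chromosome too short to hold one CGI")
    rng = substream(seed, "genome")
    chrom_lengths, cpg_positions, in_cgi = {}, {}, {}
    cgi_rows, gene_rows = [], []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        chrom_lengths[chrom] = chrom_len
        # CGI placement, non-overlapping
        n_cgi = int(round(cgi_density * chrom_len))
        intervals: list[tuple[int, int]] = []
        for _ in range(n_cgi * 4):
            if len(intervals) == n_cgi:
                break
            length = int(rng.integers(cgi_length[0], cgi_length[1] + 1))
            start = int(rng.integers(0, chrom_len - length))
            if all(start >= e + 2000 or start + length + 2000 <= s for s, e in intervals):
                intervals.append((start, start + length))
        intervals.sort()
        cgi_rows.extend((chrom, s, e) for s, e in intervals)
        # CpG walk: dense inside CGIs, sparse outside
        positions, flags = [], []
        pos = int(rng.integers(1, background_spacing + 1))
        while pos < chrom_len - 1:
            inside = any(s <= pos < e for s, e in intervals)
            positions.append(pos)
            flags.append(inside)
            if inside:
                pos += int(rng.integers(cgi_spacing[0], cgi_spacing[1] + 1))
            else:
                lo = max(2, int(0.8 * background_spacing))
                hi = max(lo + 1, int(1.2 * background_spacing))
                step = int(rng.integers(lo, hi + 1))
                # jump into a CGI if one starts before the next background CpG
                nxt = [s for s, e in intervals if pos < s < pos + step]
                pos = min(nxt) if nxt else pos + step
        cpg_positions[chrom] = np.asarray(positions, dtype=np.int64)
        in_cgi[chrom] = np.asarray(flags, dtype=bool)
        # gene placement, non-overlapping, random strand
        n_genes = int(round(gene_density * chrom_len))
        placed: list[tuple[int, int]] = []
        for _ in range(n_genes * 4):
            if len(placed) == n_genes:
                break
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            start = int(rng.integers(0, chrom_len - length))
            if all(start >= e or start + length <= s for s, e in placed):
                placed.append((start, start + length))
        placed.sort()
        for gi, (s, e) in enumerate(placed):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"{chrom}_g{gi + 1}", chrom, strand, s, e))
    return SimGenome(
        chrom_lengths,
        cpg_positions,
        in_cgi,
        pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"]),
        pd.DataFrame(gene_rows, columns=GENE_COLUMNS),
    )


def _true_levels(genome: SimGenome, level_model, rng) -> dict[str, np.ndarray]:
    a1, b1, a2, b2 = level_model
    out = {}
    for chrom, flags in genome.in_cgi.items():
        n = len(flags)
        levels = np.where(flags, rng.beta(a1, b1, size=n), rng.beta(a2, b2, size=n))
        out[chrom] = levels
    return out


def _truncated_poisson(rng, lam: float, size: int) -> np.ndarray:
    """Poisson depth conditioned on >= 1 read."""
    d = rng.poisson(lam, size=size)
    while (zero := d == 0).any():
        d[zero] = rng.poisson(lam, size=int(zero.sum()))
    return d


def _sample_track(genome, levels, depth_lambda, rng, sample_id) -> MethylomeTrack:
    frames = []
    for chrom in sorted(genome.cpg_positions):
        pos = genome.cpg_positions[chrom]
        depth = _truncated_poisson(rng, depth_lambda, len(pos))
        meth = rng.binomial(depth, levels[chrom])
        frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "unmeth": depth - meth})
        )
    return MethylomeTrack(sample_id, pd.concat(frames, ignore_index=True))


def simulate_pair(
    genome: SimGenome,
    depth_lambda: float = 30.0,
    level_model=DEFAULT_LEVEL_MODEL,
    dmr_specs: list[DMRSpec] = (),
    seed: int = 0,
    donor_id: str = "donor",
    clone_id: str = "clone",
) -> tuple[MethylomeTrack, MethylomeTrack, TruthSet]:
    """A donor/clone pair sharing true levels except at implanted DMRs.

    Clone levels are the donor levels shifted by each spec's ``delta``
    (clipped to [0, 1]); read counts are Binomial(depth, level) with depth ~
    Poisson(``depth_lambda``) truncated at >= 1, independently per sample."""
    rng = substream(seed, "pair")
    donor_levels = _true_levels(genome, level_model, rng)
    clone_levels = {c: v.copy() for c, v in donor_levels.items()}
    bed_rows = []
    for spec in dmr_specs:
        pos = genome.cpg_positions[spec.chrom]
        if spec.end_index > len(pos):
            raise ValueError(f"DMR spec exceeds CpG count on {spec.chrom}")
        sl = slice(spec.start_index, spec.end_index)
        clone_levels[spec.chrom][sl] = np.clip(donor_levels[spec.chrom][sl] + spec.delta, 0.0, 1.0)
        bed_rows.append((spec.chrom, int(pos[spec.start_index]), int(pos[spec.end_index - 1]) + 1, spec.delta))
    donor = _sample_track(genome, donor_levels, depth_lambda, rng, donor_id)
    clone = _sample_track(genome, clone_levels, depth_lambda, rng, clone_id)
    truth = TruthSet(
        pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "delta"]),
        donor_levels,
        clone_levels,
    )
    return donor, clone, truth


def simulate_null_pair(
    genome: SimGenome,
    depth_lambda: float = 30.0,
    level_model=DEFAULT_LEVEL_MODEL,
    seed: int = 0,
) -> tuple[MethylomeTrack, MethylomeTrack, TruthSet]:
    """Two independent resamplings of identical true levels (a replicate
    pair); the truth set carries no DMRs."""
    return simulate_pair(
        genome, depth_lambda, level_model, dmr_specs=(), seed=seed,
        donor_id="replicate1", clone_id="replicate2",
    )


def place_dmr_specs(
    genome: SimGenome,
    n: int,
    n_cpg: int = 10,
    delta: float = -0.4,
    seed: int = 0,
    min_gap_cpgs: int = 20,
    avoid_cgi: bool = True,
) -> list[DMRSpec]:
    """Choose ``n`` non-overlapping runs of ``n_cpg`` consecutive CpGs to
    implant, separated by at least ``min_gap_cpgs`` sites."""
    rng = substream(seed, "place_dmrs")
    chroms = sorted(genome.cpg_positions)
    specs: list[DMRSpec] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(specs) < n and attempts < 50 * n:
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        n_sites = len(genome.cpg_positions[chrom])
        if n_sites < n_cpg:
            continue
        start = int(rng.integers(0, n_sites - n_cpg + 1))
        end = start + n_cpg
        if avoid_cgi and genome.in_cgi[chrom][start:end].any():
            continue
        lo, hi = start - min_gap_cpgs, end + min_gap_cpgs
        if any(s < hi and lo < e for s, e in taken[chrom]):
            continue
        taken[chrom].append((start, end))
        specs.append(DMRSpec(chrom, start, end, delta))
    if len(specs) < n:
        raise ValueError(f"could only place {len(specs)} of {n} DMR specs")
    return sorted(specs, key=lambda s: (s.chrom, s.start_index))


def simulate_three_pairs(
    genome: SimGenome,
    depth_lambda: float = 30.0,
    level_model=DEFAULT_LEVEL_MODEL,
    pair_sd: float = 0.15,
    seed: int = 0,
) -> list[MethylomeTrack]:
    """Six tracks forming three donor-clone pairs.

    A shared base methylome is perturbed once per pair (Gaussian on the
    level scale, clipped); donor and clone of a pair are independent
    binomial resamplings of the pair's levels, so pairs are mutually more
    similar than any cross-pair combination."""
    rng = substream(seed, "three_pairs")
    base = _true_levels(genome, level_model, rng)
    tracks = []
    for pair in range(1, 4):
        pair_levels = {
            c: np.clip(v + rng.normal(0.0, pair_sd, size=len(v)), 0.0, 1.0)
            for c, v in base.items()
        }
        tracks.append(_sample_track(genome, pair_levels, depth_lambda, rng, f"donor{pair}"))
        tracks.append(_sample_track(genome, pair_levels, depth_lambda, rng, f"clone{pair}"))
    return tracks


# A synthetic BSP amplicon (not a genomic sequence): 12 CpG sites, two
# non-CpG cytosines between consecutive sites, mirroring the 12-CpG
# promoter amplicon design used for clone scoring.
_DEMO_UNIT = "CGTACTAGTTCAAT"  # one CpG + non-CpG Cs at offsets 5 and 10


def demo_amplicon(n_sites: int = 12) -> Amplicon:
    """Deterministic synthetic amplicon with ``n_sites`` CpGs."""
    seq = "ATGGATTAGGA" + _DEMO_UNIT * n_sites + "TGGATTAA"
    amp = Amplicon.from_sequence("synthetic_amplicon", seq)
    assert amp.n_sites == n_sites
    return amp


def simulate_bsp_clones(
    amplicon: Amplicon,
    site_probs,
    conversion_rate: float = 0.98,
    error_rate: float = 0.001,
    n_clones: int = 20,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate Sanger reads of bisulfite-PCR clones.

    Each clone methylates CpG site *s* with probability ``site_probs[s]``
    (methylated Cs stay C); every unmethylated C — CpG or not — converts to
    T with probability ``conversion_rate``; independent base-call errors are
    applied at ``error_rate``.  Returns (id, sequence) pairs plus a truth
    table of per-clone methylation states and realised conversion rates."""
    site_probs = np.asarray(site_probs, dtype=float)
    if len(site_probs) != amplicon.n_sites:
        raise ValueError("site_probs length must match amplicon CpG count")
    if not (0 <= conversion_rate <= 1 and 0 <= error_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = substream(seed, "bsp")
    cpg = {p: i for i, p in enumerate(amplicon.cpg_positions)}
    non_cpg = set(amplicon.non_cpg_c_positions)
    clones, truth_rows = [], []
    for k in range(n_clones):
        bases = list(amplicon.seq)
        meth_states = np.zeros(amplicon.n_sites, dtype=bool)
        n_conv = 0
        for p, i in cpg.items():
            if rng.random() < site_probs[i]:
                meth_states[i] = True  # protected C
            elif rng.random() < conversion_rate:
                bases[p] = "T"
        for p in non_cpg:
            if rng.random() < conversion_rate:
                bases[p] = "T"
                n_conv += 1
        if error_rate > 0:
            for p in range(len(bases)):
                if rng.random() < error_rate:
                    bases[p] = "ACGT"[int(rng.integers(0, 4))]
        clone_id = f"clone_{k + 1}"
        clones.append((clone_id, "".join(bases)))
        truth_rows.append(
            dict(clone_id=clone_id,
                 states="".join("M" if m else "U" for m in meth_states),
                 true_conversion=n_conv / max(len(non_cpg), 1))
        )
    return clones, pd.DataFrame(truth_rows)


def _expected_kept(v: CandidateVariant, cfg: VariantFilterConfig) -> bool:
    """Independent enumeration of the triage rules (truth for simulations)."""
    if v.donor_depth < cfg.min_depth or v.donor_depth > cfg.max_depth:
        return False
    if v.clone_depth < cfg.min_depth or v.clone_depth > cfg.max_depth:
        return False
    if v.claimed_class == "somatic":
        if v.clone_var_freq <= cfg.somatic_min_freq:
            return False
    elif v.claimed_class == "LOH":
        if cfg.loh_low <= v.clone_var_freq <= cfg.loh_high:
            return False
    else:
        return False
    return v.clone_alt_reads >= cfg.min_support


def simulate_variant_table(
    config: VariantFilterConfig | None = None,
    seed: int = 0,
    n_random: int = 40,
) -> tuple[list[CandidateVariant], pd.DataFrame]:
    """Candidate variants stratified to hit every rule boundary.

    The grid crosses depths {4, 5, 100, 101}, frequencies straddling 0.2 /
    0.25 / 0.75 and supporting-read counts {1, 2, 3}, for both claimed
    classes, plus ``n_random`` random variants.  Expected survivor flags
    come from an independent rule enumerator."""
    cfg = config or VariantFilterConfig()
    rng = substream(seed, "variants")
    bases = "ACGT"
    variants, rows = [], []
    pos = 0

    def add(claimed, d_depth, c_depth, freq, support, vartype="SNV"):
        nonlocal pos
        pos += 37
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        if vartype == "indel":
            alt = ref + bases[int(rng.integers(0, 4))]
        v = CandidateVariant(
            chrom="chr1", pos=pos, ref=ref, alt=alt, vartype=vartype,
            claimed_class=claimed, donor_depth=d_depth, clone_depth=c_depth,
            clone_alt_reads=support, clone_var_freq=freq, caller="sim",
        )
        variants.append(v)
        rows.append(dict(chrom=v.chrom, pos=v.pos, claimed_class=claimed,
                         expected_kept=_expected_kept(v, cfg)))

    boundary_depths = (cfg.min_depth - 1, cfg.min_depth, cfg.max_depth, cfg.max_depth + 1)
    freqs = (0.19, cfg.somatic_min_freq, 0.21, cfg.loh_low, 0.5,
             cfg.loh_high, 0.76)
    for claimed in ("somatic", "LOH"):
        for dd in boundary_depths:
            for cd in boundary_depths:
                for f in freqs:
                    for sup in (cfg.min_support - 1, cfg.min_support, cfg.min_support + 1):
                        add(claimed, dd, cd, f, sup)
    for _ in range(n_random):
        cd = int(rng.integers(1, 150))
        add(
            "somatic" if rng.random() < 0.5 else "LOH",
            int(rng.integers(1, 150)),
            cd,
            float(np.round(rng.random(), 3)),
            int(rng.integers(1, min(5, cd + 1))),
            "indel" if rng.random() < 0.2 else "SNV",
        )
    return variants, pd.DataFrame(rows)
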