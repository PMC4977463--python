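import pandas as pd
import pytest

from methdog.io import MethylomeTrack, PairedTrack


def paired_from_counts(rows, chrom="chr1", min_depth=4) -> PairedTrack:
    """Hand-built paired track from (pos, donor_meth, donor_unmeth,
    clone_meth, clone_unmeth) tuples."""
    df = pd.DataFrame(
        rows, columns=["pos", "donor_meth", "donor_unmeth", "clone_meth", "clone_unmeth"]
    )
    df.insert(0, "chrom", chrom)
    return PairedTrack("donor", "clone", min_depth, df)


def track_from_counts(sample_id, rows, chrom="chr1") -> MethylomeTrack:
    """Hand-built track from (pos, meth, unmeth) tuples."""
    return MethylomeTrack.from_records(
        sample_id, [(chrom, p, m, u) for p, m, u in rows]
    )


@pytest.fixture
def small_genome():
    from methdog.simulate import simulate_genome

    return simulate_genome(11, n_chrom=2, chrom_len=200_000)
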