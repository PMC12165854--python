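import numpy as np
import pytest

from shatterkit.sv_io import BreakpointJunction, CNSegment

#: compact genome for toy tests where per-base oracles must be cheap
TOY_GENOME = {"chrA": 10_000, "chrB": 8_000}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_junction(pos1, pos2, strand1="+", strand2="-", chrom1="chr21",
                  chrom2=None, **kw):
    return BreakpointJunction(
        chrom1=chrom1, pos1=pos1, strand1=strand1,
        chrom2=chrom2 or chrom1, pos2=pos2, strand2=strand2, **kw
    ).normalized()


def make_segment(start, end, cn, chrom="chr21", loh=None, sample=None):
    return CNSegment(chrom=chrom, start=start, end=end, total_cn=cn,
                     loh=loh, sample_id=sample)


def random_junctions(rng, n, chrom="chr21", lo=0, hi=1_000_000):
    out = []
    for i in range(n):
        p1, p2 = sorted(rng.integers(lo, hi, size=2).tolist())
        if p1 == p2:
            p2 += 1
        out.append(make_junction(
            int(p1), int(p2),
            strand1=rng.choice(["+", "-"]), strand2=rng.choice(["+", "-"]),
            chrom1=chrom, id=f"r{i}"))
    return out


def per_base_cn_oracle(arrangement, ploidy=2):
    """Brute-force per-base coverage; only for toy genomes (<=10 kb/chrom)."""
    genome = arrangement.genome_dict
    affected = arrangement.region[0]
    profiles = {}
    for chrom, length in genome.items():
        frags = [f for f in arrangement.fragments if f.chrom == chrom]
        if not frags:
            continue
        base = (ploidy - 1) if chrom == affected else ploidy
        cov = np.full(length, base, dtype=int)
        for f in frags:
            cov[f.start:f.end] += 1
        profiles[chrom] = cov
    return profiles
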