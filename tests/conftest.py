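import numpy as np
import pytest

from panforge.records import PairAlignmentRecord, decode_flags
from panforge.simulate import SimConfig, simulate_donors, simulate_reference


def make_record(
    read_id: str,
    flag: int,
    target: str = "*",
    pos=None,
    mapq=None,
    seq=None,
    aln_end=None,
):
    """Build a PairAlignmentRecord straight from a SAM flag integer."""
    flags = decode_flags(flag)
    mate_index = 2 if flag & 0x80 else 1
    if flags.is_unmapped:
        target, pos, mapq, aln_end = "*", None, None, None
    else:
        pos = 0 if pos is None else pos
        mapq = 60 if mapq is None else mapq
        if aln_end is None:
            aln_end = pos + (len(seq) if seq else 100)
    return PairAlignmentRecord(
        read_id=read_id,
        mate_index=mate_index,
        target=target,
        pos=pos,
        aln_end=aln_end,
        mapq=mapq,
        flags=flags,
        seq=seq,
    )


def make_pair(flag1: int, flag2: int, read_id="r", **kw):
    return (
        make_record(read_id, flag1 | 0x40, **kw),
        make_record(read_id, flag2 | 0x80, **kw),
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """A small simulated pangenome shared by unit tests (deterministic)."""
    config = SimConfig(
        ref_len=120_000,
        n_samples=2,
        insertions_per_sample=3,
        insertion_len_range=(1000, 2000),
        depth=25.0,
        seed=5,
    )
    rng = np.random.default_rng(config.seed)
    ref_rng, donor_rng = rng.spawn(2)
    reference = simulate_reference(config, ref_rng)
    donor_set = simulate_donors(reference, config, donor_rng)
    return config, reference, donor_set
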