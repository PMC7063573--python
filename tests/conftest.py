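import pytest

from epiedit.io_core import AlignedRead, GenomeRef
from epiedit.synthetic_data import make_toy_reference


@pytest.fixture(scope="session")
def toy():
    """(GenomeRef, models, sites) for the packaged toy genome."""
    return make_toy_reference(seed=0)


@pytest.fixture(scope="session")
def toy_ref(toy):
    return toy[0]


@pytest.fixture(scope="session")
def sem_model(toy):
    return next(m for m in toy[1] if m.gene_id == "semX")


@pytest.fixture(scope="session")
def cxc_model(toy):
    return next(m for m in toy[1] if m.gene_id == "cxcX")


@pytest.fixture(scope="session")
def sem_sites(toy):
    return [s for s in toy[2] if s.chrom == "chrS"]


@pytest.fixture(scope="session")
def cxc_sites(toy):
    return [s for s in toy[2] if s.chrom == "chrC"]


def make_read(chrom, pos, cigar, seq, name="r", sample="s", **kw):
    return AlignedRead(name, chrom, pos, cigar, seq, sample, **kw)


def random_read_near(rng, ref: GenomeRef, chrom: str, center: int, read_len: int = 70):
    """An internally consistent random read around *center*: random M/I/D/S
    ops with ~10% mismatching bases. Built by direct construction,
    independently of the package's segment-map machinery."""
    pos = int(center - rng.integers(20, read_len - 20))
    ops = []
    seq = []
    rpos = pos
    q_remaining = read_len
    if rng.random() < 0.2:
        n = int(rng.integers(1, 6))
        ops.append(("S", n))
        seq.append("".join("ACGT"[i] for i in rng.integers(0, 4, n)))
        q_remaining -= n
    while q_remaining > 0:
        choice = rng.random()
        if choice < 0.72 or len(ops) == 0 or ops[-1][0] != "M":
            n = int(rng.integers(1, min(25, q_remaining) + 1))
            block = []
            for g in range(rpos, rpos + n):
                base = ref.fetch(chrom, g, g)
                if rng.random() < 0.1:
                    base = "ACGT"[("ACGT".index(base) + 1 + int(rng.integers(0, 3))) % 4]
                block.append(base)
            ops.append(("M", n))
            seq.append("".join(block))
            rpos += n
            q_remaining -= n
        elif choice < 0.86:
            n = int(rng.integers(1, min(8, q_remaining) + 1))
            ops.append(("I", n))
            seq.append("".join("ACGT"[i] for i in rng.integers(0, 4, n)))
            q_remaining -= n
        else:
            n = int(rng.integers(1, 9))
            ops.append(("D", n))
            rpos += n
    # merge adjacent identical ops so the CIGAR is well-formed
    merged = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1][1] += n
        else:
            merged.append([op, n])
    if merged[-1][0] == "D":  # trailing deletion is not a valid CIGAR end
        merged.pop()
    cigar = "".join(f"{n}{op}" for op, n in merged)
    return AlignedRead("rand", chrom, pos, cigar, "".join(seq), "s")
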