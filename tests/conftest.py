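import numpy as np
import pytest

from negeseek import gen_genome, inlv1_like_config
from negeseek.simulate import GenomeConfig

#: fixed seed for the session-wide reference genome fixture
INLV1_SEED = 11


@pytest.fixture(scope="session")
def inlv1():
    """Synthetic genome mirroring the published INLV1 organization."""
    return gen_genome(inlv1_like_config(seed=INLV1_SEED))


def random_config(seed: int) -> GenomeConfig:
    """A random multi-ORF genome configuration with planted features.

    The last ORF carries the TM islands and never overlaps its
    predecessor (its hydropathy background must be under the generator's
    control); earlier junctions overlap in a different frame about half
    the time, mirroring the overlapping replicase/glycoprotein layout.
    """
    rng = np.random.default_rng(seed + 10_000)
    n_orfs = int(rng.integers(2, 4))
    utr5 = int(rng.integers(20, 61))
    orfs: list[tuple[int, int]] = []
    start = utr5 + 1
    codons = [int(rng.integers(500, 801))]
    for _ in range(n_orfs - 1):
        codons.append(int(rng.integers(230, 401)))
    for k in range(n_orfs):
        end = start + codons[k] * 3 - 1
        orfs.append((start, end))
        if k == n_orfs - 1:
            break
        if k + 1 < n_orfs - 1 and rng.random() < 0.6:
            ov = int(rng.integers(50, 200))
            nxt = end - ov + 1
            while (nxt - 1) % 3 == (start - 1) % 3:
                nxt += 1
        else:
            nxt = end + int(rng.integers(20, 100))
        start = nxt
    order = "C-A-B" if rng.random() < 0.5 else "A-B-C"
    plen = codons[0] - 1
    region_start = plen // 2 + 1
    m0 = int(rng.integers(region_start + 5, plen - 40))
    tm_plen = codons[-1] - 1
    n_islands = int(rng.integers(1, 5))
    islands: list[tuple[int, int]] = []
    pos = 40
    for _ in range(n_islands):
        if pos + 19 > tm_plen - 10:
            break
        islands.append((pos, pos + 19))
        pos += 45
    return GenomeConfig(
        length=orfs[-1][1] + int(rng.integers(20, 120)),
        gc=float(rng.uniform(0.35, 0.55)),
        orfs=orfs,
        motif_order=order,
        motif_orf=0,
        motif_aa_start=m0,
        tm_orf=n_orfs - 1,
        tm_islands=islands,
        seed=seed,
    )
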