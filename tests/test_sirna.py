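import numpy as np
import pytest

from negeseek import (GenomeRecord, ReadConfig, collapse_reads, gen_genome,
                      gen_reads, map_reads, profile, revcomp, write_profile)
from negeseek.simulate import GenomeConfig
from negeseek.sirna import hits_to_sam, read_profile, verify_hits


def _readset(seqs):
    return collapse_reads([(f"r{i}", s) for i, s in enumerate(seqs)])


def brute_map(seq, genome):
    """Scan every genome offset on both strands (independent oracle)."""
    hits = set()
    k = len(seq)
    rc = revcomp(seq)
    for i in range(len(genome) - k + 1):
        win = genome[i:i + k]
        if win == seq:
            hits.add(("+", i + 1))
        if win == rc:
            hits.add(("-", i + 1))
    return hits


@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(123)
    return GenomeRecord("g", "".join(rng.choice(list("ACGT"), size=400)))


def test_plus_strand_hit_by_construction(small_genome):
    read = small_genome.seq[10:32]   # 1-based 11..32
    hits = map_reads(_readset([read]), small_genome)
    assert ("+", 11) in {(h.strand, h.pos5) for h in hits}
    verify_hits(hits, small_genome)


def test_minus_strand_hit_by_construction(small_genome):
    read = revcomp(small_genome.seq[50:72])   # 1-based span 51..72
    hits = map_reads(_readset([read]), small_genome)
    minus = [h for h in hits if h.strand == "-"]
    assert any((h.start, h.end) == (51, 72) for h in minus)
    assert minus[0].pos5 == minus[0].end
    verify_hits(hits, small_genome)


def test_unmapped_read_absent(small_genome):
    # 22 A's are vanishingly unlikely in 400 random nt; check, then map
    probe = "A" * 22
    assert probe not in small_genome.seq and revcomp(probe) not in small_genome.seq
    assert map_reads(_readset([probe]), small_genome) == []


def test_map_reads_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(55)
    for _ in range(100):
        L = int(rng.integers(200, 2001))
        genome = GenomeRecord("g", "".join(rng.choice(list("ACGT"), size=L)))
        seqs = []
        for _ in range(15):
            k = int(rng.integers(18, 31))
            i = int(rng.integers(0, L - k + 1))
            s = genome.seq[i:i + k]
            seqs.append(s if rng.random() < 0.5 else revcomp(s))
        for _ in range(5):
            seqs.append("".join(rng.choice(list("ACGT"),
                                           size=int(rng.integers(18, 31)))))
        rs = _readset(seqs)
        hits = map_reads(rs, genome)
        got = {}
        for h in hits:
            got.setdefault(h.read_seq, set()).add((h.strand, h.start))
        for s in rs.counts:
            assert got.get(s, set()) == brute_map(s, genome.seq), s
        verify_hits(hits, genome)


def test_profile_direct_counts(small_genome):
    g = small_genome.seq
    plus = [g[i:i + 22] for i in (0, 30, 60, 90, 120, 150)]
    minus = [revcomp(g[i:i + 22]) for i in (200, 240, 280, 320)]
    rs = _readset(plus + minus)
    hits = map_reads(rs, small_genome)
    prof = profile(hits, rs, len(small_genome))
    assert prof.n_total_mapped == 10
    sd = prof.size_dist
    assert sd[(sd.length == 22)]["total"].sum() == 10
    assert sd[(sd.strand == "+")]["total"].sum() == 6
    assert sd[(sd.strand == "-")]["total"].sum() == 4
    assert prof.frac_total == 1.0


def test_profile_zero_hits_all_zero(small_genome):
    rs = _readset(["A" * 22])
    prof = profile([], rs, len(small_genome))
    assert prof.n_total_mapped == 0
    assert prof.frac_total == 0.0
    assert prof.size_dist["total"].sum() == 0
    for s in "+-":
        assert prof.coverage[s].sum() == 0.0


def test_profile_rejects_foreign_hits(small_genome):
    rs = _readset([small_genome.seq[0:22]])
    hits = map_reads(_readset([small_genome.seq[30:52]]), small_genome)
    with pytest.raises(ValueError, match="absent"):
        profile(hits, rs, len(small_genome))


def test_profile_five_prime_rna_alphabet(small_genome):
    read = "T" + small_genome.seq[101:122]
    genome2 = GenomeRecord("g2", small_genome.seq[:100] + read
                           + small_genome.seq[100 + 22:])
    rs = _readset([read])
    prof = profile(map_reads(rs, genome2), rs, len(genome2))
    fp = prof.five_prime
    assert fp[(fp.nt == "U")]["total"].sum() >= 1
    assert set(fp.nt) == {"A", "C", "G", "U"}


def test_multi_locus_read_counted_once_with_split_coverage():
    core = "ACGTTGCAACGTTGCAACGTGG"      # 22 nt, planted twice
    rng = np.random.default_rng(77)
    filler = "".join(rng.choice(list("ACGT"), size=60))
    genome = GenomeRecord("g", core + filler + core)
    assert revcomp(core) not in genome.seq
    rs = _readset([core])
    hits = map_reads(rs, genome)
    assert len(hits) == 2
    prof = profile(hits, rs, len(genome))
    assert prof.n_total_mapped == 1           # full count once in totals
    assert prof.n_multi_locus == 1
    assert prof.coverage["+"].sum() == pytest.approx(22.0)  # 0.5 weight x 2 loci
    assert prof.coverage["+"].max() == pytest.approx(0.5)


def test_palindromic_read_counted_on_plus_and_flagged():
    half = "ACGTTGCCAG"
    pal = half + revcomp(half)   # reverse-complement palindrome, 20 nt
    assert revcomp(pal) == pal
    rng = np.random.default_rng(9)
    genome = GenomeRecord("g", "".join(rng.choice(list("ACGT"), size=50))
                          + pal + "".join(rng.choice(list("ACGT"), size=50)))
    rs = _readset([pal])
    hits = map_reads(rs, genome)
    assert {h.strand for h in hits} == {"+", "-"}
    prof = profile(hits, rs, len(genome))
    assert prof.n_ambiguous_strand == 1
    sd = prof.size_dist
    assert sd[(sd.strand == "+")]["total"].sum() == 1
    assert sd[(sd.strand == "-")]["total"].sum() == 0


def test_conservation_identities_on_simulated_library():
    cfg = GenomeConfig(length=3000, orfs=[(31, 2430)], motif_order=None,
                       seed=5)
    rec, _ = gen_genome(cfg)
    sim = gen_reads(rec, ReadConfig(n_viral=2000, n_background=1000, seed=5))
    rs = sim.readset()
    hits = map_reads(rs, rec)
    prof = profile(hits, rs, len(rec))
    prof.validate()
    # total coverage mass equals sum of count x length over mapped reads
    total_cov = prof.coverage["+"].sum() + prof.coverage["-"].sum()
    mapped_mass = sum(rs.counts[s] * len(s) for s in {h.read_seq for h in hits})
    assert total_cov == pytest.approx(mapped_mass)


def test_hotspot_enriches_coverage():
    cfg = GenomeConfig(length=3000, orfs=[(31, 2430)], motif_order=None, seed=6)
    rec, _ = gen_genome(cfg)
    hotspot = (2400, 2900, 8.0)
    sim = gen_reads(rec, ReadConfig(n_viral=4000, n_background=0,
                                    hotspot=hotspot, seed=6))
    rs = sim.readset()
    prof = profile(map_reads(rs, rec), rs, len(rec))
    cov = prof.coverage["+"] + prof.coverage["-"]
    inside = cov[hotspot[0] - 1:hotspot[1]].mean()
    outside = np.concatenate([cov[:hotspot[0] - 1], cov[hotspot[1]:]]).mean()
    assert inside > 2 * outside


def test_write_read_profile_round_trip(tmp_path, small_genome):
    g = small_genome.seq
    rs = _readset([g[i:i + 22] for i in (0, 40, 80)]
                  + [revcomp(g[120:142])])
    prof = profile(map_reads(rs, small_genome), rs, len(small_genome))
    write_profile(prof, tmp_path)
    back = read_profile(tmp_path)
    assert back.n_total_mapped == prof.n_total_mapped
    assert back.frac_total == pytest.approx(prof.frac_total)
    pd_eq = (back.size_dist.reset_index(drop=True)
             == prof.size_dist.reset_index(drop=True))
    assert pd_eq.all().all()
    for s in "+-":
        assert np.allclose(back.coverage[s], prof.coverage[s])
    cov = tmp_path / "sirna_coverage.tsv"
    n_rows = sum(1 for _ in open(cov)) - 1
    assert n_rows == 2 * len(small_genome)


def test_sam_export_shape(small_genome):
    rs = _readset([small_genome.seq[5:27]])
    hits = map_reads(rs, small_genome)
    sam = hits_to_sam(hits, rs, small_genome)
    lines = sam.strip().splitlines()
    assert lines[0].startswith("@HD")
    assert lines[1] == f"@SQ\tSN:g\tLN:{len(small_genome)}"
    body = lines[2].split("\t")
    assert body[1] in ("0", "16") and body[11] == "NM:i:0"
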