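import numpy as np
import pytest

from plastidcomp.architecture import (
    RepeatHit,
    detect_inverted_repeats,
    detect_strand_switch,
    find_tandem_repeats,
    partition_quadripartite,
)
from plastidcomp.genome_model import (
    AnnotatedGenome,
    GenomeModelError,
    Interval,
    reverse_complement,
)
from plastidcomp.synthetic_data import SimConfig, simulate_genome

from conftest import make_genome


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def plant_inverted_repeat(rng, genome_len, ir_len, n_subs, ir_at, rc_at):
    """Independent planting helper: random sequence with one inverted copy
    carrying ``n_subs`` substitutions, boundaries sealed against chance
    extension."""
    seq = list(_rand_seq(rng, genome_len))
    block = _rand_seq(rng, ir_len)
    rc = list(reverse_complement(block))
    sub_pos = rng.choice(np.arange(25, ir_len - 25, 12), size=n_subs,
                         replace=False)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for p in sub_pos:
        alt = [b for b in "ACGT" if b != rc[p]]
        rc[p] = alt[int(rng.integers(0, 3))]
    seq[ir_at:ir_at + ir_len] = list(block)
    seq[rc_at:rc_at + ir_len] = rc
    # seal: 4 non-complementary bases flanking each pairing boundary
    c = ir_at + rc_at + ir_len - 1
    for t in range(4):
        for x in (ir_at - 1 - t, ir_at + ir_len + t):
            y = c - x
            if 0 <= x < genome_len and 0 <= y < genome_len:
                if seq[x] == comp[seq[y]]:
                    alt = [b for b in "ACGT"
                           if b != seq[x] and b != comp[seq[y]]]
                    seq[x] = alt[0]
    return "".join(seq)


class TestDetectInvertedRepeats:
    def test_planted_repeat_recovered_exactly(self):
        rng = np.random.default_rng(7)
        seq = plant_inverted_repeat(rng, 50_000, 5_000, 3,
                                    ir_at=10_000, rc_at=30_000)
        hits = detect_inverted_repeats(seq, min_len=1000)
        assert hits
        top = hits[0]
        assert top.length == 5000
        assert top.mismatches == 3
        assert top.interval_a == Interval(10_000, 15_000)
        assert top.interval_b == Interval(30_000, 35_000)

    def test_no_repeat_gives_empty_list(self):
        rng = np.random.default_rng(3)
        assert detect_inverted_repeats(_rand_seq(rng, 20_000)) == []

    def test_min_len_above_genome_size_empty(self):
        assert detect_inverted_repeats("ACGT" * 100, min_len=10_000) == []

    def test_symmetric_under_reverse_complement(self):
        rng = np.random.default_rng(11)
        seq = plant_inverted_repeat(rng, 30_000, 3_000, 2,
                                    ir_at=5_000, rc_at=20_000)
        fwd = detect_inverted_repeats(seq)
        rev = detect_inverted_repeats(reverse_complement(seq))
        assert fwd and rev
        assert fwd[0].length == rev[0].length
        assert fwd[0].mismatches == rev[0].mismatches

    def test_invalid_mismatch_rate(self):
        with pytest.raises(ValueError):
            detect_inverted_repeats("ACGT" * 1000, max_mismatch_rate=0.5)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_planted_truth_recovery_simulator(self, seed):
        genome, truth = simulate_genome(SimConfig(ir_mismatches=3), seed=seed)
        hits = detect_inverted_repeats(genome)
        assert hits[0].length == truth.ir["length"]
        assert hits[0].mismatches == truth.ir["mismatches"]


class TestPartitionQuadripartite:
    def _bare_circle(self, n=100):
        rng = np.random.default_rng(0)
        return AnnotatedGenome(id="c", sequence=_rand_seq(rng, n))

    def test_hand_computation(self):
        g = self._bare_circle(100)
        hit = RepeatHit(Interval(10, 20), Interval(55, 65), 10, 0)
        p = partition_quadripartite(g, hit)
        assert p.lsc == Interval(65, 10, wraps=True)  # 45 bases
        assert p.ssc == Interval(20, 55)              # 35 bases
        assert p.ssc_length() == 35
        assert p.covered_bases() == 100

    def test_adjacent_repeats_degenerate(self):
        g = self._bare_circle(100)
        hit = RepeatHit(Interval(10, 20), Interval(20, 30), 10, 0)
        p = partition_quadripartite(g, hit)
        assert p.degenerate
        assert p.ssc is None
        assert p.ssc_length() == 0
        assert p.covered_bases() == 100

    def test_linear_genome_hard_error(self):
        rng = np.random.default_rng(0)
        g = AnnotatedGenome(id="l", sequence=_rand_seq(rng, 100),
                            topology="linear")
        with pytest.raises(GenomeModelError):
            partition_quadripartite(
                g, RepeatHit(Interval(10, 20), Interval(55, 65), 10, 0))

    def test_conservation_on_simulator(self, default_sim):
        genome, truth = default_sim
        hits = detect_inverted_repeats(genome)
        p = partition_quadripartite(genome, hits)
        assert p.covered_bases() == len(genome)
        assert tuple(sorted((p.ssc_length(), p.lsc_length()))) == (
            p.ssc_length(), p.lsc_length())
        assert (p.ira.start, p.ira.end) == tuple(truth.ir["ira_span"])
        assert (p.irb.start, p.irb.end) == tuple(truth.ir["irb_span"])

    def test_insertion_block_reported(self):
        cfg = SimConfig(ir_length=5000, rrn16_length=1400,
                        rrn23_length=2200, insertion_genes=3)
        genome, truth = simulate_genome(cfg, seed=7)
        hits = detect_inverted_repeats(genome, min_len=500)
        p = partition_quadripartite(genome, hits)
        assert [(i.start, i.end) for i in p.insertions] == [
            tuple(x) for x in truth.insertions]
        assert p.ssc_length() == cfg.ssc_length
        assert p.covered_bases() == len(genome)


def _strand_oracle(strands):
    """Exhaustive best two-arc consistency score."""
    n = len(strands)
    best = 0
    for i in range(n):
        for j in range(i + 1, n + 1):
            arc1 = strands[i:j]
            arc2 = strands[j:] + strands[:i]
            sc = max(arc1.count("+"), arc1.count("-"))
            if arc2:
                sc += max(arc2.count("+"), arc2.count("-"))
            best = max(best, sc)
    return best


class TestDetectStrandSwitch:
    def test_planted_layout_30_genes(self):
        order = [(f"g{i:02d}", "+" if i < 20 else "-") for i in range(30)]
        g = make_genome(order)
        layout = detect_strand_switch(g)
        assert layout.consistency == 1.0
        assert layout.boundary_indices == (0, 20)
        assert len(layout.switch_points) == 2

    def test_all_plus_no_switch(self):
        g = make_genome([(f"g{i}", "+") for i in range(10)])
        layout = detect_strand_switch(g)
        assert layout.switch_points == []
        assert layout.consistency == 1.0

    def test_too_few_features(self):
        g = make_genome(["solo"])
        with pytest.raises(GenomeModelError):
            detect_strand_switch(g)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 41))
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
        g = make_genome(list(zip([f"g{i:02d}" for i in range(n)], strands)))
        layout = detect_strand_switch(g)
        assert layout.consistency == pytest.approx(_strand_oracle(strands) / n)

    def test_simulator_switch_recovered(self, default_sim):
        genome, truth = default_sim
        layout = detect_strand_switch(genome)
        assert layout.consistency == 1.0
        i, j = layout.boundary_indices
        ti, tj = truth.strand_boundary_indices
        assert abs(i - ti) <= 1 and abs(j - tj) <= 1


class TestFindTandemRepeats:
    def test_telomere_hand_construction(self):
        reps = find_tandem_repeats("TTAGGGTTAGGGTTAGGGTTA")
        assert len(reps) == 1
        assert reps[0].period == 6
        assert reps[0].copies == pytest.approx(3.5)
        assert reps[0].unit == "TTAGGG"

    def test_homopolymer_below_min_period_not_reported(self):
        assert find_tandem_repeats("A" * 60, min_period=5) == []

    def test_period_11_three_copies(self):
        unit = "TCAACTATTAG"
        seq = "GGCC" + unit * 3 + "CCGG"
        reps = find_tandem_repeats(seq)
        assert [(r.period, r.copies) for r in reps] == [(11, 3.0)]
        assert reps[0].start == 4

    def test_fractional_copies(self):
        unit = "ACGTTGCAACT"  # 11-mer
        # trailing GG breaks the run right after the partial fourth copy
        seq = "GG" + unit * 3 + unit[:6] + "GG"
        reps = find_tandem_repeats(seq)
        assert reps[0].period == 11
        assert round(reps[0].copies, 1) == 3.5

    def test_simulator_spacer_recovered(self, default_sim):
        genome, truth = default_sim
        lo, hi = truth.spacer_interval
        reps = find_tandem_repeats(genome.sequence[lo:hi])
        got = {(lo + r.start, r.period, round(r.copies, 1)) for r in reps}
        want = {(t["start"], t["period"], round(t["copies"], 1))
                for t in truth.tandem_repeats}
        assert want <= got
        assert got == want
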