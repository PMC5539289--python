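import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regblock.core_io import ExpressionTable, InputError, SnvRecord, TssRecord, open_genome
from regblock.mussd import (
    MutationBlock,
    assign_to_promoters,
    build_patient_sequences,
    cluster_snvs,
    filter_recurrent,
    ks_2sample,
    ks_gate,
    snv_window_sequences,
)

from conftest import write_fasta


def snv(pos, patient="P1", chrom="1", ref="A", alt="C"):
    return SnvRecord(chrom, pos, ref, alt, patient)


def brute_force_blocks(positions, max_gap):
    """Oracle: transitive closure of the pairwise |pi - pj| < max_gap relation."""
    positions = sorted(positions)
    groups = [[p] for p in positions]
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if any(abs(a - b) < max_gap for a in groups[i] for b in groups[j]):
                groups[i] += groups.pop(j)
                merged = True
                break
    return sorted(tuple(sorted(g)) for g in groups)


class TestClusterSnvs:
    def test_thirty_bp_rule(self):
        blocks = cluster_snvs([snv(100), snv(120, "P2"), snv(160)], max_gap=30)
        assert [(b.start, b.end) for b in blocks] == [(100, 120), (160, 160)]

    def test_singleton(self):
        blocks = cluster_snvs([snv(100)])
        assert len(blocks) == 1 and blocks[0].start == blocks[0].end == 100

    @pytest.mark.parametrize("second,expected", [(129, 1), (130, 2)])
    def test_strict_gap_boundary(self, second, expected):
        assert len(cluster_snvs([snv(100), snv(second)], max_gap=30)) == expected

    def test_same_position_shares_block(self):
        blocks = cluster_snvs([snv(100, "P1"), snv(100, "P2", alt="G")])
        assert len(blocks) == 1 and len(blocks[0].patients) == 2

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 51))
            positions = sorted(set(rng.integers(1, 2000, size=n).tolist()))
            got = cluster_snvs([snv(p) for p in positions], max_gap=30)
            got_groups = sorted(tuple(s.pos for s in b.snvs) for b in got)
            assert got_groups == brute_force_blocks(positions, 30)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 500), min_size=1, max_size=25), st.randoms())
    def test_order_invariance(self, positions, rnd):
        snvs = [snv(p, f"P{i % 3}") for i, p in enumerate(positions)]
        shuffled = list(snvs)
        rnd.shuffle(shuffled)
        a = [(b.start, b.end, b.patients) for b in cluster_snvs(snvs)]
        b = [(x.start, x.end, x.patients) for x in cluster_snvs(shuffled)]
        assert a == b


class TestFilterRecurrent:
    def test_single_patient_removed(self):
        blocks = cluster_snvs([snv(100), snv(110), snv(120)])
        assert filter_recurrent(blocks) == []

    def test_two_patients_kept(self):
        blocks = cluster_snvs([snv(100, "P1"), snv(110, "P2")])
        assert len(filter_recurrent(blocks)) == 1

    def test_empty(self):
        assert filter_recurrent([]) == []


class TestAssignToPromoters:
    TSS = [TssRecord("G1", "G1", "1", 5000, "+"), TssRecord("G2", "G2", "1", 5800, "+")]

    def _block(self, *positions):
        return cluster_snvs([snv(p, f"P{i}") for i, p in enumerate(positions)])[0]

    def test_assigned_inside_window(self):
        out = assign_to_promoters([self._block(4990, 5010)], self.TSS[:1])
        assert len(out) == 1 and out[0].gene_id == "G1"

    def test_dropped_outside(self):
        out = assign_to_promoters([self._block(6500, 6510)], self.TSS[:1])
        assert out == []

    def test_overlapping_promoters_duplicate(self):
        out = assign_to_promoters([self._block(5400, 5410)], self.TSS)
        assert sorted(b.gene_id for b in out) == ["G1", "G2"]


class TestKs:
    def test_identical_samples(self):
        d, p = ks_2sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_2sample([10, 11, 12, 13], [0, 0.1, 0.2, 0.3])
        assert d == 1.0

    def test_known_small_case(self):
        d, _ = ks_2sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_statistic_matches_enumeration(self, rng):
        """D equals the explicit sup over pooled points of |ECDF1 - ECDF2|."""
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 15)))
            y = rng.normal(0.5, 1.2, size=int(rng.integers(3, 15)))
            d, _ = ks_2sample(x, y)
            sup = max(
                abs((x <= t).mean() - (y <= t).mean()) for t in np.concatenate([x, y])
            )
            assert d == pytest.approx(sup, abs=1e-12)

    def test_statistic_matches_scipy(self, rng):
        from scipy.stats import ks_2samp

        x = rng.normal(size=12)
        y = rng.normal(1, 1, size=8)
        d, _ = ks_2sample(x, y)
        assert d == pytest.approx(ks_2samp(x, y).statistic)


class TestKsGate:
    def _expr(self, tumor_vals, normal_vals):
        import pandas as pd

        samples = [f"T{i}" for i in range(len(tumor_vals))] + [
            f"N{i}" for i in range(len(normal_vals))
        ]
        groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
        df = pd.DataFrame([list(tumor_vals) + list(normal_vals)], index=["G1"], columns=samples)
        return ExpressionTable(values=df, sample_groups=groups)

    def _block(self):
        b = cluster_snvs([snv(100, "P1"), snv(110, "P2")])[0]
        from dataclasses import replace

        return replace(b, gene_id="G1")

    def test_identical_distributions_kept_out(self):
        expr = self._expr([1, 2, 3, 4], [1, 2, 3, 4])
        p, keep = ks_gate(self._block(), expr)
        assert not keep and p == 1.0

    def test_disjoint_distributions_pass(self):
        expr = self._expr([10, 11, 12, 13, 14, 15], [0.1, 0.2, 0.3, 0.4])
        p, keep = ks_gate(self._block(), expr)
        assert keep and p < 0.05

    def test_missing_gene_is_error(self):
        expr = self._expr([1, 2], [3, 4])
        from dataclasses import replace

        block = replace(self._block(), gene_id="NOPE")
        with pytest.raises(InputError, match="NOPE"):
            ks_gate(block, expr)


class TestSequenceConstruction:
    @pytest.fixture()
    def genome(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        return open_genome(write_fasta(tmp_path / "g.fa", {"1": seq})), seq

    def test_patient_alt_offsets(self, genome):
        g, seq = genome
        s1 = snv(100, "P1", ref=seq[99], alt="ACGT".replace(seq[99], "")[0])
        s2 = snv(110, "P1", ref=seq[109], alt="ACGT".replace(seq[109], "")[0])
        s3 = snv(105, "P2", ref=seq[104], alt="ACGT".replace(seq[104], "")[0])
        block = cluster_snvs([s1, s2, s3])[0]
        recs = build_patient_sequences(block, g, flank=10)
        assert [r.patient_id for r in recs] == ["P1", "P2"]
        p1, p2 = recs
        assert len(p1.ref_seq) == len(p1.alt_seq) == (110 - 100 + 1) + 20
        diffs1 = [i for i, (a, b) in enumerate(zip(p1.ref_seq, p1.alt_seq)) if a != b]
        assert diffs1 == [100 - p1.seq_start, 110 - p1.seq_start]
        diffs2 = [i for i, (a, b) in enumerate(zip(p2.ref_seq, p2.alt_seq)) if a != b]
        assert diffs2 == [105 - p2.seq_start]

    def test_reference_mismatch_is_error(self, genome):
        g, seq = genome
        wrong_ref = "ACGT".replace(seq[99], "")[0]
        alt = "ACGT".replace(wrong_ref, "")[0]
        block = cluster_snvs(
            [snv(100, "P1", ref=wrong_ref, alt=alt), snv(105, "P2", ref=seq[104], alt="ACGT".replace(seq[104], "")[0])]
        )[0]
        with pytest.raises(InputError, match="does not match"):
            build_patient_sequences(block, g, flank=5)

    def test_snv_window_61bp(self, genome):
        g, seq = genome
        s = snv(200, ref=seq[199], alt="ACGT".replace(seq[199], "")[0])
        ref, alt = snv_window_sequences(s, g, half=30)
        assert len(ref) == len(alt) == 61
        assert ref[30] == s.ref_base and alt[30] == s.alt_base
        assert ref[:30] == alt[:30] and ref[31:] == alt[31:]

    def test_snv_window_zero_half(self, genome):
        g, seq = genome
        s = snv(200, ref=seq[199], alt="ACGT".replace(seq[199], "")[0])
        assert snv_window_sequences(s, g, half=0) == (s.ref_base, s.alt_base)

    def test_snv_window_clipped(self, genome):
        g, seq = genome
        s = snv(10, ref=seq[9], alt="ACGT".replace(seq[9], "")[0])
        ref, alt = snv_window_sequences(s, g, half=30)
        assert len(ref) == 40  # positions 1..40
        assert ref[9] == s.ref_base and alt[9] == s.alt_base
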