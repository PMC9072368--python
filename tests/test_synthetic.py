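"""Generator contracts: determinism, planted truth, noise model, folding."""
from __future__ import annotations

import io as _io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m5cdevmap import classify, synthetic
from m5cdevmap.io import write_fasta
from m5cdevmap.models import SimulationConfig, TruthSite, transcript_index
from m5cdevmap.synthetic import (
    CapacityError,
    LengthParams,
    fold_minimal,
    make_species_pair,
    make_transcriptome,
    plant_truth,
    simulate_reads,
)


def fasta_bytes(transcriptome) -> bytes:
    buf = _io.StringIO()
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(t.sequence), id=t.transcript_id, description="") for t in transcriptome],
        buf, "fasta",
    )
    return buf.getvalue().encode()


class TestMakeTranscriptome:
    def test_fixed_lengths_sum(self):
        (t,) = make_transcriptome(1, LengthParams(50, 300, 100), seed=7)
        assert len(t.sequence) == 450
        assert (t.utr5_len, t.cds_len, t.utr3_len) == (50, 300, 100)

    def test_deterministic_for_seed(self):
        a = make_transcriptome(5, LengthParams(), seed=42)
        b = make_transcriptome(5, LengthParams(), seed=42)
        assert fasta_bytes(a) == fasta_bytes(b)
        c = make_transcriptome(5, LengthParams(), seed=43)
        assert fasta_bytes(a) != fasta_bytes(c)

    def test_gc_gradient_realized(self):
        targets = np.linspace(0.60, 0.40, 10)  # falling 5' -> 3'
        tx = make_transcriptome(200, LengthParams(100, 500, 400), gc_gradient=targets, seed=1)
        n_bins = len(targets)
        gc = np.zeros(n_bins)
        total = np.zeros(n_bins)
        for t in tx:
            edges = np.linspace(0, len(t.sequence), n_bins + 1)
            for b in range(n_bins):
                chunk = t.sequence[int(edges[b]) : int(edges[b + 1])]
                total[b] += len(chunk)
                gc[b] += sum(ch in "GC" for ch in chunk)
        realized = gc / total
        assert realized[0] > realized[-1]
        assert np.all(np.abs(realized - targets) < 0.03)

    def test_invalid_length_spec(self):
        with pytest.raises(ValueError):
            make_transcriptome(1, LengthParams(utr5=(10, 5)), seed=0)
        with pytest.raises(ValueError):
            make_transcriptome(1, LengthParams(cds=0), seed=0)
        with pytest.raises(ValueError):
            make_transcriptome(0, LengthParams(), seed=0)


class TestPlantTruth:
    def test_sites_are_c_with_planted_motif(self, small_transcriptome):
        tx = small_transcriptome()
        truth = plant_truth(tx, 40, type_mix=0.5, seed=9)
        index = transcript_index(tx)
        assert len(truth) == 40
        for s in truth:
            seq = index[s.transcript_id].sequence
            assert seq[s.position] == "C"
            down = seq[s.position + 1 : s.position + 5]
            if s.planted_type == "TypeII":
                assert down[0] == "U" and down[1] == "C" and down[3] == "A"
            else:
                assert seq[s.position + 1 : s.position + 4] == "GGG"

    def test_classifier_round_trip(self, small_transcriptome):
        tx = small_transcriptome()
        truth = plant_truth(tx, 50, type_mix=0.4, seed=2)
        index = transcript_index(tx)
        for s in truth:
            ctx = classify.extract_context(index[s.transcript_id], s.position)
            assert classify.classify_site(ctx) == s.planted_type

    def test_type_mix_within_binomial_error(self, small_transcriptome):
        tx = small_transcriptome(n_genes=100, lengths=LengthParams(150, 1500, 550))
        truth = plant_truth(tx, 1000, type_mix=0.237, seed=5, min_spacing=60)
        frac = np.mean([s.planted_type == "TypeII" for s in truth])
        se = np.sqrt(0.237 * 0.763 / 1000)
        assert abs(frac - 0.237) < 3 * se

    def test_point_mass_levels(self, small_transcriptome):
        tx = small_transcriptome()
        truth = plant_truth(tx, 10, level_dist=0.5, seed=1)
        assert all(s.true_level == 0.5 for s in truth)

    def test_capacity_error(self, small_transcriptome):
        tx = small_transcriptome(n_genes=1)
        with pytest.raises(CapacityError):
            plant_truth(tx, 10_000, seed=0)


class TestSimulateReads:
    def test_perfect_conversion_no_truth(self, small_transcriptome):
        tx = small_transcriptome(n_genes=3)
        cfg = SimulationConfig(conversion_rate=1.0, bad_read_fraction=0.0, seed=8)
        reads = simulate_reads(tx, [], cfg)
        assert reads.n_obs > 0
        assert not reads.obs_state_c.any()

    def test_nonsite_fraction_binomial_oracle(self, small_transcriptome):
        tx = small_transcriptome(n_genes=1, lengths=LengthParams(100, 500, 400))
        cfg = SimulationConfig(
            conversion_rate=0.995, bad_read_fraction=0.0, coverage_mean=300, seed=12
        )
        reads = simulate_reads(tx, [], cfg)
        n = reads.n_obs
        frac = reads.obs_state_c.mean()
        se = np.sqrt(0.005 * 0.995 / n)
        assert abs(frac - 0.005) < 3 * se

    def test_site_level_recovered(self, small_transcriptome):
        tx = small_transcriptome(n_genes=1)
        truth = plant_truth(tx, 3, level_dist=0.5, seed=3)
        cfg = SimulationConfig(conversion_rate=1.0, bad_read_fraction=0.0,
                               coverage_mean=400, seed=4)
        reads = simulate_reads(tx, truth, cfg)
        for s in truth:
            at = reads.obs_pos == s.position
            n = int(at.sum())
            frac = reads.obs_state_c[at].mean()
            assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_bad_reads_all_unconverted(self, small_transcriptome):
        tx = small_transcriptome(n_genes=2)
        cfg = SimulationConfig(conversion_rate=1.0, bad_read_fraction=0.3, seed=6)
        reads = simulate_reads(tx, [], cfg)
        ccounts = reads.per_read_c_counts()
        totals = np.bincount(reads.obs_read, minlength=reads.n_reads)
        # every read is either fully converted or fully unconverted
        assert np.all((ccounts == 0) | (ccounts == totals))

    def test_coverage_and_quality_contract(self, small_transcriptome):
        tx = small_transcriptome(n_genes=2, lengths=LengthParams(100, 800, 300))
        cfg = SimulationConfig(coverage_mean=60, seed=7)
        reads = simulate_reads(tx, [], cfg)
        assert (reads.obs_qual >= 30).mean() >= 0.985
        index = transcript_index(tx)
        # conservation: observations lie on reference Cs within bounds
        for code, tid in enumerate(reads.transcript_ids):
            on = reads.obs_tid == code
            seq = index[tid].sequence
            positions = reads.obs_pos[on]
            assert positions.min() >= 0 and positions.max() < len(seq)
            assert all(seq[p] == "C" for p in positions[:200])
        cov = np.zeros(0)
        for code, tid in enumerate(reads.transcript_ids):
            L = len(index[tid].sequence)
            counts = np.bincount(reads.obs_pos[reads.obs_tid == code], minlength=L)
            c_mask = np.frombuffer(index[tid].sequence.encode(), np.uint8) == ord("C")
            cov = np.concatenate([cov, counts[c_mask]])
        assert abs(cov.mean() - 60) / 60 < 0.10

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads([], [], SimulationConfig())

    def test_deterministic(self, small_transcriptome):
        tx = small_transcriptome(n_genes=2)
        a = simulate_reads(tx, [], SimulationConfig(seed=5))
        b = simulate_reads(tx, [], SimulationConfig(seed=5))
        assert np.array_equal(a.obs_pos, b.obs_pos)
        assert np.array_equal(a.obs_state_c, b.obs_state_c)
        assert np.array_equal(a.obs_qual, b.obs_qual)


def _enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Brute-force optimum of the maximum-pairing recursion (oracle)."""
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        options = [best(i, j - 1)]
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in pairs:
                options.append(best(i, k - 1) + 1 + best(k + 1, j - 1))
        return max(options)

    return best(0, len(seq) - 1)


class TestFoldMinimal:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGGAAACCC", "(((...)))"), ("AAAAA", "....."), ("GC", "..")],
    )
    def test_examples(self, seq, expected):
        assert fold_minimal(seq) == expected

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            fold_minimal("GATTACA")  # DNA: T not allowed

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=0, max_size=14))
    def test_matches_enumeration_oracle_and_is_valid(self, seq):
        db = fold_minimal(seq)
        assert len(db) == len(seq)
        # balanced, min-loop respected, pair count optimal
        stack = []
        n_pairs = 0
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                assert i - j > 3
                assert (seq[j], seq[i]) in {
                    ("A", "U"), ("U", "A"), ("G", "C"),
                    ("C", "G"), ("G", "U"), ("U", "G"),
                }
                n_pairs += 1
        assert not stack
        assert n_pairs == _enumerate_max_pairs(seq)


class TestMakeSpeciesPair:
    def test_zero_substitution_identity(self, small_transcriptome):
        tx = small_transcriptome(n_genes=3)
        truth = plant_truth(tx, 10, seed=1)
        pair = make_species_pair(tx, truth, sub_rate=0.0, seed=2)
        omap = pair.ortholog_map
        assert (omap.posA == omap.posB).all()
        assert (omap.baseA == omap.baseB).all()
        assert not any(r.forced_lost for r in pair.sites)

    def test_null_coefficients_half_retention(self, small_transcriptome):
        tx = small_transcriptome(n_genes=60, lengths=LengthParams(150, 1500, 550))
        truth = plant_truth(tx, 1000, seed=3, min_spacing=60)
        pair = make_species_pair(tx, truth, sub_rate=0.0, glm_coefs={}, seed=4)
        frac = np.mean([r.retained for r in pair.sites])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_site_substitution_forces_loss(self, small_transcriptome):
        tx = small_transcriptome(n_genes=5)
        truth = plant_truth(tx, 20, seed=5)
        pair = make_species_pair(tx, truth, sub_rate=0.2, seed=6)
        for r in pair.sites:
            if r.base_b != "C":
                assert r.forced_lost and not r.retained

    def test_negative_base_coefficient_drives_loss(self, small_transcriptome):
        tx = small_transcriptome(n_genes=60, lengths=LengthParams(150, 1500, 550))
        truth = plant_truth(tx, 800, type_mix=0.0, seed=7, min_spacing=60)
        pair = make_species_pair(
            tx, truth, sub_rate=0.05,
            glm_coefs={"intercept": 2.0, "base+1_U": -4.0}, seed=8,
        )
        with_u = [r for r in pair.sites if not r.forced_lost and r.features["base+1_U"] == 1.0]
        without_u = [r for r in pair.sites if not r.forced_lost and r.features["base+1_U"] == 0.0]
        loss_u = np.mean([not r.retained for r in with_u])
        loss_other = np.mean([not r.retained for r in without_u])
        assert loss_u > loss_other + 0.3

    def test_substitution_rate_realized(self, small_transcriptome):
        tx = small_transcriptome(n_genes=5)
        truth = plant_truth(tx, 5, seed=9)
        pair = make_species_pair(tx, truth, sub_rate=0.1, seed=10)
        omap = pair.ortholog_map
        rate = (omap.baseA != omap.baseB).mean()
        assert abs(rate - 0.1) < 3 * np.sqrt(0.1 * 0.9 / len(omap))
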