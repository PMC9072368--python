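"""Site-caller kernels against independent oracles, plus the filter cascade."""
from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from m5cdevmap import caller, synthetic
from m5cdevmap.caller import (
    CallerConfig,
    apply_c_cutoff,
    binomial_site_test,
    call_sites,
    estimate_gene_conversion,
    gini_coefficient,
    pileup_from_reads,
    select_c_cutoff,
    signal_ratio,
    stouffer_combine,
)
from m5cdevmap.models import ReadCytosineRecord, SimulationConfig
from m5cdevmap.synthetic import LengthParams


# --------------------------------------------------------------------------
# kernels vs independent oracles
# --------------------------------------------------------------------------

def gini_pairwise_oracle(values):
    x = list(values)
    n = len(x)
    mad = sum(abs(a - b) for a in x for b in x) / (n * n)
    return mad / (2 * sum(x) / n)


class TestGini:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 1, 1, 1], 0.0), ([0, 1], 0.5), ([0, 0, 0, 1], 0.75)],
    )
    def test_examples(self, values, expected):
        assert gini_coefficient(values) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=30)
        .filter(lambda xs: sum(xs) > 0)
    )
    def test_matches_pairwise_oracle(self, values):
        assert gini_coefficient(values) == pytest.approx(
            gini_pairwise_oracle(values), abs=1e-12
        )

    def test_undefined_inputs(self):
        with pytest.raises(ValueError):
            gini_coefficient([])
        with pytest.raises(ValueError):
            gini_coefficient([0.0, 0.0])


def binomial_tail_oracle(c, n, p):
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(c, n + 1))


class TestBinomialSiteTest:
    @pytest.mark.parametrize(
        "c,n,p,expected",
        [
            (0, 20, 0.005, 1.0),
            (20, 20, 0.005, 0.005**20),
            (3, 20, 0.005, binomial_tail_oracle(3, 20, 0.005)),
        ],
    )
    def test_examples(self, c, n, p, expected):
        assert binomial_site_test(c, n, p) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(min_value=1, max_value=60),
        st.floats(min_value=1e-4, max_value=0.5),
        st.data(),
    )
    def test_matches_summation_oracle(self, n, p, data):
        c = data.draw(st.integers(min_value=0, max_value=n))
        assert binomial_site_test(c, n, p) == pytest.approx(
            binomial_tail_oracle(c, n, p), abs=1e-12
        )

    def test_monotone_in_c_count(self):
        ps = [binomial_site_test(c, 30, 0.01) for c in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            binomial_site_test(1, 10, 0.0)
        with pytest.raises(ValueError):
            binomial_site_test(1, 10, 1.0)
        with pytest.raises(ValueError):
            binomial_site_test(11, 10, 0.5)


def stouffer_oracle(p1, p2):
    """Closed form via erfc, independent of scipy.stats.norm."""
    def isf(p):  # inverse upper-tail of the standard normal by bisection
        lo, hi = -40.0, 40.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if 0.5 * math.erfc(mid / math.sqrt(2)) > p:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    z = (isf(p1) + isf(p2)) / math.sqrt(2)
    return 0.5 * math.erfc(z / math.sqrt(2))


class TestStouffer:
    def test_null_midpoint(self):
        assert stouffer_combine(0.5, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_known_value(self):
        # sqrt(2) * z(0.05) combined: ~0.0100
        assert stouffer_combine(0.05, 0.05) == pytest.approx(
            stouffer_oracle(0.05, 0.05), abs=1e-10
        )

    @pytest.mark.parametrize("p1,p2", [(0.05, 0.5), (0.001, 0.9), (0.3, 0.0004)])
    def test_matches_erfc_oracle_and_symmetry(self, p1, p2):
        assert stouffer_combine(p1, p2) == pytest.approx(
            stouffer_oracle(p1, p2), abs=1e-10
        )
        assert stouffer_combine(p1, p2) == stouffer_combine(p2, p1)

    def test_domain_errors(self):
        for bad in [(0.0, 0.5), (0.5, 1.0), (-0.1, 0.5)]:
            with pytest.raises(ValueError):
                stouffer_combine(*bad)


# --------------------------------------------------------------------------
# read-level operations
# --------------------------------------------------------------------------

def reads_at(n_c, n_t, pos=10, qual=37, tid="tx1", extra_c=0, start_id=0):
    """n_c unconverted + n_t converted reads at one position; ``extra_c``
    adds that many additional unconverted Cs to each C-read (elsewhere)."""
    out = []
    for i in range(n_c):
        obs = [(pos, "C", qual)] + [(pos + 20 + j, "C", qual) for j in range(extra_c)]
        out.append(ReadCytosineRecord(f"c{start_id + i}", tid, obs))
    for i in range(n_t):
        out.append(ReadCytosineRecord(f"t{start_id + i}", tid, [(pos, "T", qual)]))
    return out


class TestPileup:
    def test_counts_exact(self):
        pil = pileup_from_reads(reads_at(3, 0), 30)
        assert pil[("tx1", 10)].c_count_hq == 3
        assert pil[("tx1", 10)].t_count_hq == 0

    def test_low_quality_excluded_from_hq(self):
        pil = pileup_from_reads(
            [ReadCytosineRecord("r", "tx1", [(10, "C", 20)])], 30
        )
        assert pil[("tx1", 10)].c_count_hq == 0
        assert pil[("tx1", 10)].c_count_all == 1

    def test_empty_stream(self):
        assert pileup_from_reads([], 30) == {}


class TestCCutoff:
    def test_over_cutoff_removed(self):
        reads = [ReadCytosineRecord("r", "tx1", [(i * 10, "C", 37) for i in range(5)])]
        kept, log = apply_c_cutoff(reads, 3)
        assert kept.n_reads == 0 and log.n_removed == 1

    def test_boundary_retained(self):
        reads = [ReadCytosineRecord("r", "tx1", [(i * 10, "C", 37) for i in range(3)])]
        kept, log = apply_c_cutoff(reads, 3)
        assert kept.n_reads == 1 and log.n_removed == 0

    def test_zero_cutoff_keeps_c_free_read(self):
        reads = [ReadCytosineRecord("r", "tx1", [(4, "T", 37)])]
        kept, _ = apply_c_cutoff(reads, 0)
        assert kept.n_reads == 1


class TestSignalRatio:
    def test_no_removal(self):
        assert signal_ratio(("tx1", 10), reads_at(10, 10), cutoff=3) == 1.0

    def test_two_of_ten_removed(self):
        reads = reads_at(8, 10) + reads_at(2, 0, extra_c=4, start_id=50)
        assert signal_ratio(("tx1", 10), reads, cutoff=3) == pytest.approx(0.8)

    def test_boundary_inclusive(self):
        reads = reads_at(9, 10) + reads_at(1, 0, extra_c=4, start_id=50)
        assert signal_ratio(("tx1", 10), reads, cutoff=3) == pytest.approx(0.9)

    def test_no_c_observations_error(self):
        with pytest.raises(ValueError):
            signal_ratio(("tx1", 10), reads_at(0, 5), cutoff=3)


def background_reads(tid, n_positions, per_pos_c, per_pos_t, qual=37, base_pos=1000):
    """Converted background: per position, per_pos_c unconverted and
    per_pos_t converted singleton reads."""
    out = []
    for p in range(n_positions):
        pos = base_pos + p * 7
        for i in range(per_pos_c):
            out.append(ReadCytosineRecord(f"{tid}bgc{p}.{i}", tid, [(pos, "C", qual)]))
        for i in range(per_pos_t):
            out.append(ReadCytosineRecord(f"{tid}bgt{p}.{i}", tid, [(pos, "T", qual)]))
    return out


class TestGeneConversion:
    def test_rate_arithmetic(self):
        # 995 converted + 5 unconverted observations in total
        reads = background_reads("tx1", 9, 0, 100) + background_reads(
            "tx1", 1, 5, 95, base_pos=5000
        )
        stats_by_gene = estimate_gene_conversion(reads, set(), {"tx1": "g1"})
        g = stats_by_gene["g1"]
        assert g.conversion_rate == pytest.approx(0.995)
        assert not g.resistant and not g.low_confidence

    def test_all_candidates_gives_global_rate(self):
        reads = background_reads("tx1", 2, 5, 45) + background_reads("tx2", 10, 0, 100)
        cands = {("tx1", 1000), ("tx1", 1007)}
        out = estimate_gene_conversion(
            reads, cands, {"tx1": "g1", "tx2": "g2"}
        )
        assert out["g1"].low_confidence
        assert out["g1"].rate_used == pytest.approx(out["g2"].rate_used)

    def test_resistant_gene_flagged(self):
        reads = background_reads("tx1", 20, 1, 9)  # 10% non-conversion, 200 obs
        out = estimate_gene_conversion(reads, set(), {"tx1": "g1"})
        assert out["g1"].resistant


class TestSelectCCutoff:
    def test_identical_filtered_sets_choose_smaller(self):
        # no read exceeds one unconverted C: every cutoff >= 1 is equivalent
        reads = reads_at(10, 30)
        chosen, diag = select_c_cutoff(reads, [1, 2, 3])
        assert chosen == 1
        assert diag.gini.nunique() == 1

    def test_requires_two_cutoffs(self):
        with pytest.raises(ValueError):
            select_c_cutoff(reads_at(5, 5), [3])

    def test_stabilizes_on_noisy_simulation(self, small_transcriptome):
        tx = small_transcriptome(n_genes=30, lengths=LengthParams(150, 1500, 550))
        truth = synthetic.plant_truth(tx, 120, seed=1)
        cfg = SimulationConfig(bad_read_fraction=0.2, seed=1)
        reads = synthetic.simulate_reads(tx, truth, cfg)
        chosen, diag = select_c_cutoff(reads, [1, 2, 3, 4, 6, 10, 20, 40])
        assert chosen is not None and chosen <= 4
        # removing conversion-failure reads reshapes candidate levels
        # monotonically: the Gini trend has a single direction
        g = diag.gini.to_numpy()
        diffs = np.diff(g)
        assert np.all(diffs <= 1e-9) or np.all(diffs >= -1e-9)


# --------------------------------------------------------------------------
# the cascade on crafted fixtures
# --------------------------------------------------------------------------

GENE = {"tx1": "g1"}


def clean_background(n_pos=30, rate=0.0, start_id=0):
    """Gene background with the requested non-conversion rate (per mille)."""
    per_c = int(rate * 20)
    return background_reads("tx1", n_pos, per_c, 20 - per_c)


def audit_row(audit, pos):
    rows = audit[(audit.transcript_id == "tx1") & (audit.position == pos)]
    assert len(rows) == 1, f"expected exactly one audit row at {pos}"
    return rows.iloc[0]


class TestFilterCascadeTruthTable:
    """Each cascade filter violated in isolation is the recorded first failure."""

    def run(self, rep1, rep2=None, **cfg):
        reps = [rep1] if rep2 is None else [rep1, rep2]
        return call_sites(reps, GENE, CallerConfig(**cfg))

    def test_passing_site_emitted(self):
        rep = reads_at(30, 30) + clean_background()
        sites, audit = self.run(rep, rep)
        assert audit_row(audit, 10).emitted
        (site,) = sites
        assert site.level == pytest.approx(0.5)
        assert site.combined_p is not None and site.combined_p < 0.001

    def test_coverage_first_fail(self):
        rep = reads_at(10, 9) + clean_background()
        _, audit = self.run(rep, rep)
        assert audit_row(audit, 10).first_fail == "coverage"

    def test_variant_count_first_fail(self):
        # 2 high-quality Cs; low-quality Cs keep the position a candidate
        rep = reads_at(2, 48) + reads_at(10, 0, qual=20, start_id=60) + clean_background()
        _, audit = self.run(rep, rep)
        assert audit_row(audit, 10).first_fail == "variant_count"

    def test_level_first_fail(self):
        # high-quality level 5/60 < 0.1 but all-quality level >= 0.1
        rep = reads_at(5, 55) + reads_at(4, 0, qual=20, start_id=60) + clean_background()
        _, audit = self.run(rep, rep)
        assert audit_row(audit, 10).first_fail == "level"

    def test_c_cutoff_first_fail(self):
        # 30 Cs of 282; removing 3 over-C reads drops the level below 0.1
        # while the signal ratio stays at the inclusive 0.9 boundary
        rep = reads_at(27, 252) + reads_at(3, 0, extra_c=4, start_id=60) + clean_background()
        _, audit = self.run(rep, rep)
        assert audit_row(audit, 10).first_fail == "c_cutoff"

    def test_signal_ratio_first_fail(self):
        # 4 of 30 C-reads removed: ratio 0.867 < 0.9, level still 26/56
        rep = reads_at(26, 30) + reads_at(4, 0, extra_c=4, start_id=60) + clean_background()
        _, audit = self.run(rep, rep)
        assert audit_row(audit, 10).first_fail == "signal_ratio"

    def test_resistant_gene_first_fail(self):
        # gene-wide non-conversion ~8.3% (> 5%) over plenty of observations,
        # per-position background levels kept below candidacy
        bg = background_reads("tx1", 30, 5, 55)
        rep = reads_at(30, 30) + bg
        _, audit = self.run(rep, rep)
        assert audit_row(audit, 10).first_fail == "resistant_gene"

    def test_binomial_p_first_fail(self):
        # non-conversion 4% (not resistant); 3/20 Cs give p ~ 0.044
        bg = background_reads("tx1", 50, 2, 48)
        rep = reads_at(3, 17) + bg
        _, audit = self.run(rep, rep)
        assert audit_row(audit, 10).first_fail == "binomial_p"

    def test_replicate_combined_p_first_fail(self):
        # rep1 passes alone (p ~ 2.6e-4 at 5% background); rep2 is present
        # (level 0.1) but weak, dragging the combined p above 1e-3
        bg = background_reads("tx1", 100, 1, 19)
        rep1 = reads_at(6, 14) + bg
        rep2 = reads_at(2, 18) + bg
        _, audit = self.run(rep1, rep2)
        row = audit_row(audit, 10)
        assert row.first_fail == "replicate"
        assert row.combined_p is not None and row.combined_p >= 0.001

    def test_replicate_presence_first_fail(self):
        # rep2 covered but level far below presence
        rep1 = reads_at(30, 30) + clean_background()
        rep2 = reads_at(1, 59) + clean_background()
        _, audit = self.run(rep1, rep2)
        assert audit_row(audit, 10).first_fail == "replicate"

    def test_single_replicate_needs_five_variants(self):
        bg = clean_background()
        rep1 = reads_at(4, 36) + bg
        rep2 = bg  # site not covered at all in rep2
        _, audit = self.run(rep1, rep2)
        assert audit_row(audit, 10).first_fail == "replicate"
        rep1b = reads_at(5, 35) + bg
        sites, audit2 = self.run(rep1b, rep2)
        assert audit_row(audit2, 10).emitted
        assert sites[0].combined_p is None

    def test_audit_partition(self):
        rep = reads_at(30, 30) + reads_at(10, 9, pos=200, start_id=80) + clean_background()
        sites, audit = self.run(rep, rep)
        assert audit.emitted.sum() == len(sites)
        assert (audit.first_fail.notna() == ~audit.emitted).all()
        assert not audit.duplicated(["transcript_id", "position"]).any()


def test_bed_export_round_trip():
    from m5cdevmap.caller import sites_to_bed

    rep = reads_at(30, 30) + clean_background()
    sites, _ = call_sites([rep, rep], GENE, CallerConfig())
    bed = sites_to_bed(sites)
    assert list(bed.columns) == ["chrom", "start", "end", "name", "score", "strand"]
    assert (bed.end - bed.start == 1).all()
    assert bed.score.iloc[0] == 500  # level 0.5 scaled to 0-1000


class TestThresholdMonotonicity:
    def test_call_count_non_increasing_as_thresholds_tighten(self, fidelity_run):
        base = len(fidelity_run.sites)
        for change in [
            {"min_coverage": 30}, {"min_level": 0.2},
            {"min_variant_reads": 6}, {"min_signal_ratio": 0.95},
            {"p_threshold": 1e-5},
        ]:
            sites, _ = call_sites(
                fidelity_run.replicates, fidelity_run.transcriptome,
                CallerConfig(**change),
            )
            assert len(sites) <= base
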