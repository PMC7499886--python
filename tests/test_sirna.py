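"""Multimapper reassignment, RPM tracks, per-TE sums, metaplot geometry."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from temdyn.sirna import (
    AlignmentError,
    AlignmentRecord,
    AlignmentTable,
    SignalTrack,
    first_base_composition,
    metaplot_matrix,
    normalize_rpm,
    quantify_te,
    reassign_multimappers,
    total_genome_matching,
)


def rec(rid, cands, length=24, first="A", count=1):
    return AlignmentRecord(rid, length, first, count, tuple(cands))


CHROMS = {"chr1": 10_000}


class TestReassign:
    def test_unique_read_weight_one(self):
        out = reassign_multimappers([rec("r", [("chr1", 100, "+")])], CHROMS)
        assert out[0].weights == (1.0,)

    def test_symmetric_multimapper_uniform(self):
        out = reassign_multimappers(
            [rec("m", [("chr1", 100, "+"), ("chr1", 500, "+")])], CHROMS
        )
        assert out[0].weights == pytest.approx((0.5, 0.5))

    def test_nine_to_one_fixed_point(self):
        """Hand-iterated oracle: w1 <- (9 + w1) / 11 converges to 0.9."""
        reads = [rec(f"u{i}", [("chr1", 100, "+")]) for i in range(9)]
        reads.append(rec("u9", [("chr1", 500, "+")]))
        reads.append(rec("m", [("chr1", 100, "+"), ("chr1", 500, "+")]))
        w1 = 0.5
        for _ in range(300):
            w1 = (9 + w1) / 11
        out = reassign_multimappers(reads, CHROMS)
        got = next(w for w in out if w.read_id == "m")
        assert got.weights[0] == pytest.approx(w1, abs=1e-6)
        assert got.weights[1] == pytest.approx(1 - w1, abs=1e-6)

    def test_empty_candidates_rejected(self):
        with pytest.raises(AlignmentError, match="empty candidate"):
            AlignmentRecord("x", 24, "A", 1, ())

    def test_mass_conserved_and_identity_on_unique(self, small_world, small_config):
        from temdyn.synthetic import simulate_sirna_reads

        ann, truth = small_world
        cfg = small_config.replace(frac_multimapping=0.0)
        tab = simulate_sirna_reads(ann, truth, "lh", 1, cfg)
        out = reassign_multimappers(tab, ann.chrom_sizes)
        assert (out.cands["weight"] == 1.0).all()
        # conservation: sum of weighted mass == number of reads (counts incl.)
        mass = (out.cands["weight"].to_numpy()
                * out.reads["count"].to_numpy()[out.cands["read_idx"]]).sum()
        assert mass == pytest.approx(tab.total_count())

    def test_order_invariance(self, small_world, small_config):
        from temdyn.synthetic import simulate_sirna_reads

        ann, truth = small_world
        tab = simulate_sirna_reads(ann, truth, "et", 1, small_config)
        out1 = reassign_multimappers(tab, ann.chrom_sizes)
        perm = np.random.default_rng(0).permutation(len(tab.reads))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = AlignmentTable(
            reads=tab.reads.iloc[perm].reset_index(drop=True),
            cands=tab.cands.assign(read_idx=inv[tab.cands["read_idx"]])
            .sort_values(["read_idx"], kind="stable").reset_index(drop=True),
        )
        out2 = reassign_multimappers(shuffled, ann.chrom_sizes)
        w1 = out1.cands.sort_values(["read_idx", "start"])["weight"].to_numpy()
        lookup = out2.cands.assign(orig=perm[out2.cands["read_idx"]])
        w2 = lookup.sort_values(["orig", "start"])["weight"].to_numpy()
        assert np.allclose(w1, w2, atol=1e-9)

    def test_true_origin_recovery_with_skewed_coverage(self):
        """>= 90% of multimapper mass lands on true loci at 9:1 skew."""
        rng = np.random.default_rng(5)
        reads = []
        for fam in range(20):
            true_pos = 200 + fam * 400
            decoy_pos = 200 + fam * 400 + 8000
            for i in range(12):
                reads.append(rec(f"u{fam}_{i}", [("chr1", true_pos, "+")]))
            reads.append(rec(f"d{fam}", [("chr1", decoy_pos, "+")]))
            order = rng.permutation(2)
            cands = [("chr1", true_pos, "+"), ("chr1", decoy_pos, "+")]
            reads.append(rec(f"m{fam}", [cands[j] for j in order]))
        out = reassign_multimappers(reads, {"chr1": 20_000})
        mass_true = mass_all = 0.0
        for w in out:
            if not w.read_id.startswith("m"):
                continue
            for weight, cand in zip(w.weights, w.record.candidates):
                mass_all += weight
                if (cand[1] - 200) % 400 == 0 and cand[1] < 8000 + 200:
                    mass_true += weight
        assert mass_true / mass_all >= 0.90

    @given(st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 4), st.integers(1, 3)),
        min_size=1, max_size=25,
    ))
    def test_weights_always_sum_to_one(self, read_specs):
        reads = []
        for i, (pos, ncand, count) in enumerate(read_specs):
            cands = [("chr1", pos + 37 * j, "+") for j in range(ncand)]
            reads.append(rec(f"r{i}", cands, count=count))
        out = reassign_multimappers(reads, {"chr1": 2_000})
        for w in out:
            assert sum(w.weights) == pytest.approx(1.0, abs=1e-9)


class TestNormalizeQuantify:
    def test_single_read_rpm(self):
        out = reassign_multimappers([rec("r", [("chr1", 50, "+")])], CHROMS)
        track = normalize_rpm(out, 10 ** 6, CHROMS)
        assert track.values["chr1"][50] == pytest.approx(1.0)

    def test_scale_invariance(self):
        reads = [rec("r", [("chr1", 50, "+")], count=5)]
        t1 = normalize_rpm(reassign_multimappers(reads, CHROMS), 1000, CHROMS)
        reads2 = [rec("r", [("chr1", 50, "+")], count=10)]
        t2 = normalize_rpm(reassign_multimappers(reads2, CHROMS), 2000, CHROMS)
        assert t1.values["chr1"][50] == pytest.approx(t2.values["chr1"][50])

    def test_zero_total_rejected(self):
        out = reassign_multimappers([rec("r", [("chr1", 50, "+")])], CHROMS)
        with pytest.raises(AlignmentError):
            normalize_rpm(out, 0, CHROMS)

    def test_quantify_half_open_and_additive(self):
        ann = pd.DataFrame({"te_id": ["TE1"], "chrom": ["chr1"],
                            "start": [100], "end": [200]})
        values = {"chr1": np.zeros(10_000)}
        values["chr1"][99] = 0.7    # 1 bp before start: excluded
        values["chr1"][100] = 0.5   # at start: included
        values["chr1"][150] = 0.5
        values["chr1"][199] = 0.25  # last included base
        values["chr1"][200] = 9.0   # at end: excluded
        got = quantify_te(SignalTrack(values=values), ann)
        assert got["TE1"] == pytest.approx(1.25)

    def test_quantify_no_reads_zero(self):
        ann = pd.DataFrame({"te_id": ["TE1"], "chrom": ["chr1"],
                            "start": [0], "end": [50]})
        got = quantify_te(SignalTrack(values={"chr1": np.zeros(100)}), ann)
        assert got["TE1"] == 0.0

    def test_inverted_size_range_rejected(self):
        ann = pd.DataFrame({"te_id": ["TE1"], "chrom": ["chr1"],
                            "start": [0], "end": [50]})
        with pytest.raises(AlignmentError):
            quantify_te(SignalTrack(values={"chr1": np.zeros(100)}), ann, (30, 24))


class TestFirstBase:
    def test_fractions(self):
        reads = [rec("a", [("chr1", 0, "+")], first="A"),
                 rec("b", [("chr1", 5, "+")], first="A"),
                 rec("c", [("chr1", 9, "+")], first="A"),
                 rec("d", [("chr1", 12, "+")], first="G")]
        assert first_base_composition(reads, 24) == pytest.approx({"A": 0.75, "G": 0.25})

    def test_count_weighting_and_empty(self):
        reads = [rec("a", [("chr1", 0, "+")], first="C", count=10)]
        assert first_base_composition(reads, 24) == {"C": 1.0}
        assert first_base_composition(reads, 21) == {}

    def test_sums_to_one_on_library(self, small_world, small_config):
        from temdyn.synthetic import simulate_sirna_reads

        ann, truth = small_world
        tab = simulate_sirna_reads(ann, truth, "lt", 3, small_config)
        comp = first_base_composition(tab, 24)
        assert sum(comp.values()) == pytest.approx(1.0)


class TestMetaplot:
    def constant_track(self, value=2.0, n=30_000):
        return SignalTrack(values={"chr1": np.full(n, value)})

    def test_constant_track_constant_bins_and_1600_columns(self):
        regions = pd.DataFrame({"te_id": ["r1"], "chrom": ["chr1"],
                                "start": [12_000], "end": [15_000], "strand": ["+"]})
        m = metaplot_matrix(self.constant_track(), regions)
        assert m.values.shape == (1, 1600)
        assert np.allclose(m.values, 2.0)

    def test_minus_strand_reversed(self):
        n = 3_000
        vals = {"chr1": np.arange(n, dtype=float)}
        regions_p = pd.DataFrame({"te_id": ["p"], "chrom": ["chr1"],
                                  "start": [1_000], "end": [2_000], "strand": ["+"]})
        regions_m = regions_p.assign(te_id=["m"], strand=["-"])
        kw = dict(bin_size=10, body_length=500, upstream=100, downstream=100)
        mp = metaplot_matrix(SignalTrack(values=vals), regions_p, **kw)
        mm = metaplot_matrix(SignalTrack(values=vals), regions_m, **kw)
        assert np.allclose(mm.values[0], mp.values[0][::-1])

    def test_short_region_no_crash(self):
        regions = pd.DataFrame({"te_id": ["tiny"], "chrom": ["chr1"],
                                "start": [100], "end": [103], "strand": ["+"]})
        m = metaplot_matrix(self.constant_track(3.0, 1_000), regions,
                            bin_size=5, body_length=100, upstream=10, downstream=10)
        assert np.allclose(m.values[0], 3.0)

    def test_bad_bin_divisibility(self):
        regions = pd.DataFrame({"te_id": ["r"], "chrom": ["chr1"],
                                "start": [0], "end": [10], "strand": ["+"]})
        with pytest.raises(AlignmentError):
            metaplot_matrix(self.constant_track(1.0, 100), regions,
                            bin_size=7, body_length=100, upstream=10, downstream=10)
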