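"""Readthrough index, strain comparison, defective calls and summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from termindex import (
    GeneSet,
    SignalTrack,
    associate_rti,
    compare_gene_rti,
    compare_strains,
    compute_rti,
    compute_rti_table,
    defective_fraction,
    expression_filter,
    strain_summaries,
)
from helpers import (
    brute_force_window_count,
    make_gene,
    random_sparse_track,
    welch_t_oracle,
)


class TestComputeRTI:
    def test_perfect_termination_gives_zero(self):
        g = make_gene(polya=2000)
        t = SignalTrack("s")
        t.set_interval("chrI", "+", 1, 2000, 3)  # nothing past the poly(A) site
        rec = compute_rti(t, g)
        assert rec.rti == 0.0 and rec.downstream_count == 0

    def test_uniform_window_ratio(self):
        """4 reads/nt upstream, 1 read/nt downstream: RTI = 450/1800 = 0.25."""
        g = make_gene(polya=2000)
        t = SignalTrack("s")
        t.set_interval("chrI", "+", 1, 2000, 4)
        t.set_interval("chrI", "+", 2001, 2600, 1)
        rec = compute_rti(t, g)
        assert rec.upstream_count == 1800 and rec.downstream_count == 450
        assert rec.rti == 0.25

    def test_zero_upstream_yields_missing(self):
        g = make_gene(polya=2000)
        t = SignalTrack("s")
        t.set_interval("chrI", "+", 2051, 2500, 1)
        assert compute_rti(t, g).rti is None
        assert compute_rti(t, g, pseudocount=1.0).rti == pytest.approx(451.0)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_on_sparse_fixtures(self, rng, strand):
        g = make_gene(strand=strand, polya=2500)
        for _ in range(10):
            t = random_sparse_track(rng, strand=strand, span=5000)
            rec = compute_rti(t, g)
            up = brute_force_window_count(t, g, -500, -51)
            down = brute_force_window_count(t, g, 51, 500)
            assert rec.upstream_count == up and rec.downstream_count == down
            if up:
                assert rec.rti == down / up

    def test_scale_invariance(self, rng):
        """Multiplying every count by a positive integer leaves RTI unchanged."""
        g = make_gene(polya=2500)
        t = random_sparse_track(rng, span=5000)
        base = compute_rti(t, g)
        for k in (2, 7, 100):
            scaled = compute_rti(t.scaled(k), g)
            assert scaled.rti == base.rti
            assert scaled.upstream_count == k * base.upstream_count


class TestExpressionFilter:
    def _tracks_with_density(self, g, densities):
        tracks = []
        for i, d in enumerate(densities):
            t = SignalTrack(f"s{i}", strain="WT" if i < 3 else "mut", replicate=i % 3 + 1)
            total = int(round(d * g.cds_length))
            # spread `total` reads evenly with the remainder at the CDS start
            base, extra = divmod(total, g.cds_length)
            if base:
                t.set_interval(g.chrom, g.strand, g.cds_start, g.cds_end, base)
            for p in range(g.cds_start, g.cds_start + extra):
                t.add(g.chrom, g.strand, p, 1)
            tracks.append(t)
        return tracks

    def test_density_one_in_three_of_six_samples_retained(self):
        g = make_gene(polya=2000, body=1000)
        tracks = self._tracks_with_density(g, [1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
        assert expression_filter(tracks, GeneSet([g])).gene_ids == [g.gene_id]

    def test_density_just_below_threshold_removed(self):
        g = make_gene(polya=2000, body=1000)
        tracks = self._tracks_with_density(g, [0.99] * 6)
        assert len(expression_filter(tracks, GeneSet([g]))) == 0

    def test_all_zero_dataset_empty(self):
        g = make_gene(polya=2000)
        tracks = [SignalTrack(f"s{i}") for i in range(6)]
        assert len(expression_filter(tracks, GeneSet([g]))) == 0


class TestCompareGeneRTI:
    def test_identical_replicates_null(self):
        vals = [0.02, 0.03, 0.04]
        c = compare_gene_rti("g", vals, vals)
        assert c.log2_ratio == 0.0
        assert c.p_value == pytest.approx(0.5)
        assert c.defective is False

    def test_strong_increase_matches_welch_oracle(self):
        wt = [0.01, 0.01, 0.01]
        mut = [0.08, 0.09, 0.10]
        c = compare_gene_rti("g", wt, mut)
        assert c.log2_ratio == pytest.approx(math.log2(9))
        assert c.p_value == pytest.approx(welch_t_oracle(mut, wt, "greater"), abs=1e-12)
        assert c.defective is True

    def test_one_sidedness(self):
        c = compare_gene_rti("g", [0.08, 0.09, 0.10], [0.01, 0.012, 0.011])
        assert c.log2_ratio < 0
        assert c.p_value > 0.5
        assert c.defective is False

    def test_eligibility_minimums(self):
        # 2+2 = 4 total < 5: undetermined
        c = compare_gene_rti("g", [0.01, 0.02], [0.1, 0.2])
        assert c.defective is None and c.p_value is None
        # 1 WT replicate: undetermined even with 5 total
        c = compare_gene_rti("g", [0.01], [0.1, 0.2, 0.3, 0.4])
        assert c.defective is None
        # 2+3 = 5: determined
        c = compare_gene_rti("g", [0.01, 0.012], [0.1, 0.2, 0.3])
        assert c.defective is not None

    def test_missing_rtis_excluded_from_replicates(self):
        c = compare_gene_rti("g", [0.01, None, 0.012], [0.1, 0.2, 0.3])
        assert c.n_wt == 2 and c.n_mut == 3

    def test_zero_wt_mean_gives_infinite_ratio(self):
        c = compare_gene_rti("g", [0.0, 0.0, 0.0], [0.1, 0.2, 0.3])
        assert c.log2_ratio == math.inf
        assert c.defective is True  # inf > threshold, p < alpha


class TestDefectiveFraction:
    def _comp_frame(self, flags):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(flags))],
            "defective": flags,
        })

    def test_all_and_none(self):
        frac, n_def, n = defective_fraction(self._comp_frame([True] * 4))
        assert (frac, n_def, n) == (1.0, 4, 4)
        frac, n_def, n = defective_fraction(self._comp_frame([False] * 4))
        assert (frac, n_def, n) == (0.0, 0, 4)

    def test_undetermined_excluded_from_denominator(self):
        frac, n_def, n = defective_fraction(self._comp_frame([True, False, None, None]))
        assert (frac, n_def, n) == (0.5, 1, 2)

    def test_no_determined_genes_errors(self):
        with pytest.raises(ValueError):
            defective_fraction(self._comp_frame([None, None]))

    def test_planted_cohort_recovery(self, small_cohort):
        """The planted defective genes (large effect) are the called genes."""
        _, genes, truth, wt, mut = small_cohort
        table = compute_rti_table(wt + mut, genes)
        comp = compare_strains(table)
        frac, n_def, n = defective_fraction(comp)
        assert n == len(genes)
        called = comp.set_index("gene_id")["defective"].astype(bool)
        planted = truth.set_index("gene_id")["true_defective"].reindex(called.index)
        assert (called == planted).mean() >= 0.9
        assert abs(frac - planted.mean()) <= 0.1


class TestStrainSummaries:
    def test_identical_strains(self):
        rows = []
        for i, v in enumerate([0.01, 0.02, 0.03, 0.04, 0.05]):
            for strain in ("WT", "mut"):
                rows.append({"gene_id": f"g{i}", "sample_id": f"{strain}1",
                             "strain": strain, "replicate": 1, "rti": v})
        s = strain_summaries(pd.DataFrame(rows))
        assert s["WT"].mean_rti == s["mut"].mean_rti
        assert s["WT"].mean_comparison_p == 1.0
        assert s["WT"].median_comparison_p == 1.0

    def test_hand_computed_five_gene_fixture(self):
        wt_vals = {"g1": 0.01, "g2": 0.02, "g3": 0.03, "g4": 0.04, "g5": 0.10}
        mut_vals = {"g1": 0.05, "g2": 0.06, "g3": 0.07, "g4": 0.20, "g5": 0.30}
        rows = []
        for gid in wt_vals:
            rows.append({"gene_id": gid, "sample_id": "w1", "strain": "WT",
                         "replicate": 1, "rti": wt_vals[gid]})
            rows.append({"gene_id": gid, "sample_id": "m1", "strain": "mut",
                         "replicate": 1, "rti": mut_vals[gid]})
        s = strain_summaries(pd.DataFrame(rows))
        assert s["WT"].mean_rti == pytest.approx(np.mean(list(wt_vals.values())))
        assert s["WT"].median_rti == pytest.approx(0.03)
        assert s["mut"].median_rti == pytest.approx(0.07)
        assert s["WT"].q1 <= s["WT"].median_rti <= s["WT"].q3
        from helpers import paired_t_oracle
        assert s["WT"].mean_comparison_p == pytest.approx(
            paired_t_oracle(list(mut_vals.values()), list(wt_vals.values())), abs=1e-12)
        assert s["WT"].median_comparison_p == pytest.approx(
            welch_t_oracle(list(mut_vals.values()), list(wt_vals.values())), abs=1e-12)

    def test_single_strain_without_pvalues(self):
        rows = [{"gene_id": f"g{i}", "sample_id": "w1", "strain": "WT",
                 "replicate": 1, "rti": 0.01 * (i + 1)} for i in range(4)]
        s = strain_summaries(pd.DataFrame(rows))
        assert s["WT"].mean_comparison_p is None
        assert s["WT"].median_comparison_p is None

    def test_replicate_means_feed_gene_level_stats(self):
        """Per-gene aggregation averages replicate RTIs first."""
        rows = []
        for rep, v in enumerate([0.01, 0.03], start=1):
            rows.append({"gene_id": "g1", "sample_id": f"w{rep}", "strain": "WT",
                         "replicate": rep, "rti": v})
        for rep, v in enumerate([0.05, 0.07], start=1):
            rows.append({"gene_id": "g2", "sample_id": f"w{rep}", "strain": "WT",
                         "replicate": rep, "rti": v})
        s = strain_summaries(pd.DataFrame(rows))
        assert s["WT"].mean_rti == pytest.approx(np.mean([0.02, 0.06]))


class TestAssociateRTI:
    def test_constant_feature_errors(self):
        v = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            associate_rti(v, pd.Series([5.0, 5.0, 5.0], index=v.index))

    def test_single_class_errors(self):
        v = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            associate_rti(v, pd.Series(["TATA"] * 3, index=v.index))

    def test_identical_class_distributions_give_p_one(self):
        v = pd.Series([0.1, 0.2, 0.1, 0.2], index=list("abcd"))
        f = pd.Series(["TATA", "TATA", "TATA-less", "TATA-less"], index=list("abcd"))
        rep = associate_rti(v, f)
        assert rep["p_value"] == pytest.approx(1.0)
        assert rep["classes"]["TATA"]["mean"] == rep["classes"]["TATA-less"]["mean"]

    def test_planted_monotone_length_relation_detected(self, rng):
        lengths = pd.Series(np.linspace(500, 5000, 60),
                            index=[f"g{i}" for i in range(60)])
        rti = pd.Series(0.01 + lengths.to_numpy() * 1e-5
                        + rng.normal(0, 0.003, size=60), index=lengths.index)
        rep = associate_rti(rti, lengths)
        assert rep["kind"] == "numeric"
        assert rep["rho"] > 0
        assert rep["p_value"] < 0.05
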