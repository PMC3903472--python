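"""Aberration calling: fold filtering, segmentation, gene intersection and
cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from oncoclade import cgh
from oncoclade.synthetic import CohortConfig, emit_probe_track, generate_cohort


def iv(fold, sample="s1", chrom="chr1", start=0, end=1000, direction=None):
    return cgh.IntervalCall(sample, chrom, start, end, fold, direction)


class TestFilterByFold:
    def test_boundaries_strict(self):
        calls = [iv(0.79), iv(0.8), iv(1.0), iv(1.2), iv(1.21), iv(1.25)]
        kept = cgh.filter_by_fold(calls)
        assert [(c.fold_change, c.direction) for c in kept] == [
            (0.79, "loss"), (1.21, "gain"), (1.25, "gain")]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        folds = rng.uniform(0.3, 3.0, size=200)
        calls = [iv(float(f)) for f in folds]
        kept = cgh.filter_by_fold(calls)
        expect = [f for f in folds if f > 1.2 or f < 0.8]
        assert [c.fold_change for c in kept] == pytest.approx(expect)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        calls = [iv(float(f)) for f in rng.uniform(0.3, 3.0, size=100)]
        once = cgh.filter_by_fold(calls)
        twice = cgh.filter_by_fold(once)
        assert once == twice

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cgh.filter_by_fold([], gain_fold=0.9, loss_fold=1.1)

    def test_accepts_dataframe(self):
        df = pd.DataFrame([{"sample": "s1", "chrom": "chr1", "start": 0,
                            "end": 10, "fold_change": 1.5}])
        (c,) = cgh.filter_by_fold(df)
        assert c.direction == "gain"


class TestSegmentation:
    def test_noiseless_exact_recovery(self):
        planted = pd.DataFrame([
            {"chrom": "chr1", "start": 1_000_000, "end": 2_000_000, "fold_change": 1.5}])
        track = emit_probe_track(planted, 10_000, 0.0, seed=0)
        (call,) = cgh.segment_probes(track, 200_000, 2.5)
        assert (call.chrom, call.start, call.end) == ("chr1", 1_000_000, 2_000_000)
        assert call.fold_change == pytest.approx(1.5)

    def test_probe_count_in_interval(self):
        planted = pd.DataFrame([
            {"chrom": "chr2", "start": 3_000_000, "end": 4_000_000, "fold_change": 1.5}])
        track = emit_probe_track(planted, 10_000, 0.0, seed=0)
        sub = track[(track.chrom == "chr2")]
        covered = sub[(sub.pos >= 3_000_000) & (sub.pos < 4_000_000)]
        assert len(covered) == 100
        assert np.allclose(covered["log2_ratio"], np.log2(1.5))

    def test_all_zero_track_no_calls(self):
        track = emit_probe_track(pd.DataFrame(columns=["chrom", "start", "end", "fold_change"]),
                                 25_000, 0.0, seed=0)
        assert cgh.segment_probes(track, 200_000, 2.5) == []
        assert np.allclose(track["log2_ratio"], 0.0)

    def test_empty_track(self):
        empty = pd.DataFrame(columns=["chrom", "pos", "log2_ratio"])
        assert cgh.segment_probes(empty, 200_000, 2.5) == []

    def test_unsorted_rejected(self):
        track = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 50],
                              "log2_ratio": [0.0, 0.0]})
        with pytest.raises(ValueError, match="sorted"):
            cgh.segment_probes(track, 1_000, 2.5)

    def test_noisy_recovery_rate(self):
        """Planted 1 Mb fold-1.5 interval, noise_sd 0.2: recovered with >=50%
        reciprocal overlap in >=95% of 40 replicates (seeded subsample of the
        full 200-replicate acceptance sweep)."""
        planted = pd.DataFrame([
            {"chrom": "chr1", "start": 4_000_000, "end": 5_000_000, "fold_change": 1.5}])
        hits = 0
        for seed in range(40):
            track = emit_probe_track(planted, 10_000, 0.2, seed=seed)
            calls = cgh.filter_by_fold(cgh.segment_probes(track, 200_000, 2.5))
            for c in calls:
                if c.chrom != "chr1" or c.direction != "gain":
                    continue
                inter = min(c.end, 5_000_000) - max(c.start, 4_000_000)
                if inter >= 0.5 * 1_000_000 and inter >= 0.5 * (c.end - c.start):
                    hits += 1
                    break
        assert hits >= 38


class TestIntersectGenes:
    ANN = [cgh.GeneAnnotation("G1", "chr1", 100, 200),
           cgh.GeneAnnotation("G2", "chr2", 100, 200)]

    def test_containment(self):
        calls = cgh.filter_by_fold([iv(1.5, start=0, end=1000)])
        (e,) = cgh.intersect_genes(calls, self.ANN)
        assert (e.gene, e.direction) == ("G1", "gain")

    def test_one_bp_overlap_half_open(self):
        calls = cgh.filter_by_fold([iv(1.5, start=199, end=300)])
        assert [e.gene for e in cgh.intersect_genes(calls, self.ANN)] == ["G1"]
        calls = cgh.filter_by_fold([iv(1.5, start=200, end=300)])
        assert cgh.intersect_genes(calls, self.ANN) == []

    def test_unknown_chrom_warns_not_raises(self, caplog):
        calls = cgh.filter_by_fold([iv(1.5, chrom="chrZ")])
        with caplog.at_level("WARNING"):
            assert cgh.intersect_genes(calls, self.ANN) == []
        assert any("chrZ" in r.message for r in caplog.records)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        genes = [cgh.GeneAnnotation(f"g{i}", f"chr{rng.integers(1, 4)}",
                                    s := int(rng.integers(0, 10_000)),
                                    s + int(rng.integers(1, 500)))
                 for i in range(50)]
        calls = cgh.filter_by_fold(
            [iv(float(rng.choice([0.5, 1.5])), sample=f"s{rng.integers(3)}",
                chrom=f"chr{rng.integers(1, 4)}",
                start=(st := int(rng.integers(0, 10_000))),
                end=st + int(rng.integers(1, 800)))
             for _ in range(50)])
        got = {(e.sample, e.gene, e.direction)
               for e in cgh.intersect_genes(calls, genes)}
        expect = {(c.sample, g.gene, c.direction)
                  for c in calls for g in genes
                  if g.chrom == c.chrom and c.start < g.end and g.start < c.end}
        assert got == expect


class TestSummaries:
    def test_empty_calls_zero_table(self):
        clin = pd.DataFrame({"sample": ["a"], "sex": ["M"]})
        tab = cgh.chromosome_summary([], clin)
        assert (tab.to_numpy() == 0).all()
        assert list(tab.index)[:2] == ["chr1", "chr2"]

    def test_direct_count(self):
        clin = pd.DataFrame({"sample": ["a"], "sex": ["M"]})
        calls = cgh.filter_by_fold(
            [iv(1.5, "a"), iv(1.5, "a"), iv(1.5, "a"), iv(0.5, "a"), iv(0.5, "a")])
        row = cgh.chromosome_summary(calls, clin).loc["chr1"]
        assert (row["total"], row["amplifications"], row["deletions"]) == (5, 3, 2)
        assert (row["amp_males"], row["del_males"]) == (3, 2)
        assert (row["amp_females"], row["del_females"]) == (0, 0)

    def test_conservation_against_per_sample_totals(self, small_cohort):
        calls = cgh.filter_by_fold(small_cohort.interval_reports)
        tab = cgh.chromosome_summary(calls, small_cohort.samples)
        totals = cgh.per_sample_totals(calls)
        assert tab["total"].sum() == sum(totals.values())
        assert (tab["total"] == tab["amplifications"] + tab["deletions"]).all()

    def test_unknown_sex_rejected(self):
        clin = pd.DataFrame({"sample": ["a"], "sex": ["?"]})
        with pytest.raises(ValueError, match="sex"):
            cgh.chromosome_summary(cgh.filter_by_fold([iv(1.5, "a")]), clin)

    def test_per_sample_totals_track_planted_counts(self):
        cohort = generate_cohort(CohortConfig(n_samples=8, seed=5, emit_probe_tracks=False))
        calls = cgh.filter_by_fold(cohort.interval_reports)
        totals = cgh.per_sample_totals(calls, samples=list(cohort.samples["sample"]))
        planted = {t["sample"]: t["n_intervals"] for t in cohort.truth["samples"]}
        assert totals == planted

    def test_per_sample_totals_empty(self):
        assert cgh.per_sample_totals([]) == {}
        assert cgh.per_sample_totals([], samples=["x"]) == {"x": 0}
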