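import numpy as np
import pytest

from oracles import brute_revcomp, brute_tiling, component_count, nw_identity, nw_score
from ribotile.coverage_regions import AbundantRegion
from ribotile.probe_design import (
    DesignConfig,
    deduplicate_regions,
    design_matrix,
    design_probe_set,
    pairwise_identity,
    pool_name,
    pool_samples,
    rank_and_select,
    select_learning_samples,
    tile_probes,
)
from ribotile.read_triage import PartitionReport
from ribotile.records import reverse_complement
from ribotile.synthetic_data import mutate_sequence, random_sequence


def _region(seq, start=0, ref_id="refA", median=1000.0, sample_id="s1"):
    return AbundantRegion(ref_id, start, start + len(seq), seq, median, sample_id)


def _report(sample_id, rrna_frac):
    rest = 1 - rrna_frac
    return PartitionReport(
        sample_id,
        counts={"rRNA": int(rrna_frac * 1000), "host": 0, "retained": int(rest * 1000)},
        fractions={"rRNA": rrna_frac, "host": 0.0, "retained": rest},
    )


class TestLearningSampleSelection:
    def test_strictly_above_threshold_descending(self):
        reports = [_report("A", 0.45), _report("B", 0.10), _report("C", 0.31)]
        assert select_learning_samples(reports, 0.30) == ["A", "C"]

    def test_all_below(self):
        assert select_learning_samples([_report("A", 0.1)], 0.30) == []

    def test_boundary_excluded(self):
        assert select_learning_samples([_report("A", 0.30)], 0.30) == []

    def test_empty_sample_skipped(self):
        empty = PartitionReport("E", {"rRNA": 0, "host": 0, "retained": 0}, None)
        assert select_learning_samples([empty, _report("A", 0.4)], 0.30) == ["A"]


class TestRankAndSelect:
    def test_top2_by_median(self):
        regions = [
            _region("A" * 60, median=900.0),
            _region("C" * 60, start=100, median=700.0),
            _region("G" * 60, start=200, median=800.0),
        ]
        got = rank_and_select(regions, 2)
        assert [r.median_depth for r in got] == [900.0, 800.0]

    def test_top_n_larger_than_count(self):
        regions = [_region("A" * 60)]
        assert rank_and_select(regions, 50) == regions

    def test_invalid_top_n(self):
        with pytest.raises(ValueError):
            rank_and_select([], 0)

    def test_matches_sort_oracle_with_ties(self, rng):
        regions = []
        for i in range(100):
            start = int(rng.integers(0, 5000))
            regions.append(
                _region(
                    random_sequence(60, rng),
                    start=start,
                    ref_id=f"ref{int(rng.integers(0, 5))}",
                    median=float(rng.integers(1, 10) * 100),  # forces ties
                )
            )
        for top_n in (1, 7, 50, 200):
            expected = sorted(regions, key=lambda r: (-r.median_depth, r.ref_id, r.start))[:top_n]
            assert rank_and_select(regions, top_n) == expected


def test_pool_samples_is_concatenation():
    a = [_region("A" * 60, sample_id="s1")] * 20
    b = [_region("C" * 60, sample_id="s2")] * 20
    pooled = pool_samples([a, [], b])
    assert len(pooled) == 40
    assert pooled == a + b


class TestPairwiseIdentity:
    def test_identical(self, rng):
        seq = random_sequence(100, rng)
        assert pairwise_identity(seq, seq) == 1.0

    def test_simple_mismatch(self):
        assert pairwise_identity("ACGT", "ACGA") == 0.75

    def test_symmetry(self, rng):
        a, b = random_sequence(80, rng), random_sequence(90, rng)
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_planted_substitutions(self, rng):
        # 10% substitutions, no indels: the optimal alignment is the
        # gap-free diagonal and its identity is uniquely determined
        for trial in range(10):
            a = random_sequence(150, rng)
            b = mutate_sequence(a, 0.10, seed=int(rng.integers(0, 2**31 - 1)))
            assert pairwise_identity(a, b) == pytest.approx(nw_identity(a, b))

    def test_score_matches_dp_oracle_with_indels(self, rng):
        # with indels the identity of co-optimal alignments can differ,
        # but the optimal score is unique — check it through the identity
        # relation score = 3*matches + mismatches - (len(a)+len(b))
        for trial in range(5):
            a = random_sequence(60, rng)
            b = a[:20] + a[25:50] + random_sequence(12, rng)
            from ribotile.probe_design import _aligner

            aln = _aligner().align(a, b)[0]
            assert aln.score == nw_score(a, b)


class TestDeduplicateRegions:
    def test_identical_pair_collapses(self, rng):
        seq = random_sequence(80, rng)
        regions = [_region(seq, sample_id="s1"), _region(seq, sample_id="s2")]
        assert len(deduplicate_regions(regions, 0.80, seed=3)) == 1

    def test_component_structure(self, rng):
        a = random_sequence(100, rng)
        b = mutate_sequence(a, 0.10, seed=9)  # ~90% identity with a
        c = random_sequence(100, rng)  # unrelated
        regions = [_region(a), _region(b, start=200), _region(c, start=400)]
        for seed in range(5):
            retained = deduplicate_regions(regions, 0.80, seed=seed)
            assert len(retained) == 2
            assert regions[2] in retained

    def test_deterministic_per_seed(self, rng):
        regions = [
            _region(random_sequence(80, rng), start=i * 100) for i in range(6)
        ]
        base = mutate_sequence(regions[0].sequence, 0.05, seed=1)
        regions.append(_region(base, start=900))
        a = deduplicate_regions(regions, 0.80, seed=11)
        b = deduplicate_regions(regions, 0.80, seed=11)
        assert a == b

    def test_matches_component_oracle_on_planted_clusters(self, rng):
        for trial in range(20):
            regions = []
            k = 0
            for cluster in range(int(rng.integers(1, 4))):
                base = random_sequence(70, rng)
                for member in range(int(rng.integers(1, 4))):
                    seq = mutate_sequence(base, 0.05, seed=int(rng.integers(0, 2**31 - 1)))
                    regions.append(_region(seq, start=k * 100))
                    k += 1
            for single in range(int(rng.integers(0, 3))):
                regions.append(_region(random_sequence(70, rng), start=k * 100))
                k += 1
            edges = [
                (i, j)
                for i in range(len(regions))
                for j in range(i + 1, len(regions))
                if nw_identity(regions[i].sequence, regions[j].sequence) >= 0.80
            ]
            expected = component_count(len(regions), edges)
            retained = deduplicate_regions(regions, 0.80, seed=trial)
            assert len(retained) == expected
            # soundness: no retained pair is redundant
            for i in range(len(retained)):
                for j in range(i + 1, len(retained)):
                    assert pairwise_identity(retained[i].sequence, retained[j].sequence) < 0.80


class TestTileProbes:
    def test_two_probes_region_150_gap_50(self, rng):
        region = _region(random_sequence(150, rng), start=10)
        probes = tile_probes(region, 50, 50)
        assert [(p.target_start, p.target_end) for p in probes] == [(10, 60), (110, 160)]

    def test_region_shorter_than_probe(self, rng):
        assert tile_probes(_region(random_sequence(49, rng)), 50, 25) == []

    def test_seven_probes_region_500_gap_25(self, rng):
        region = _region(random_sequence(500, rng))
        probes = tile_probes(region, 50, 25)
        assert len(probes) == 7
        assert [(p.target_start, p.target_end) for p in probes] == brute_tiling(500, 50, 25)

    def test_antisense_sequence(self):
        region = _region("AACG", median=100.0)
        probes = tile_probes(region, 4, 0)
        assert probes[0].sequence == "CGTT"

    def test_probe_naming(self, rng):
        region = _region(random_sequence(60, rng), start=7, ref_id="refX")
        assert tile_probes(region, 50, 25)[0].probe_id == "refX:7-57"

    def test_invalid_probe_length(self, rng):
        with pytest.raises(ValueError):
            tile_probes(_region(random_sequence(60, rng)), 0, 25)

    def test_tiling_soundness(self, rng):
        region = _region(random_sequence(777, rng), start=13)
        gap, length = 30, 50
        probes = tile_probes(region, length, gap)
        for a, b in zip(probes, probes[1:]):
            assert b.target_start - a.target_end == gap
        for p in probes:
            assert region.start <= p.target_start < p.target_end <= region.end
            window = region.sequence[p.target_start - region.start : p.target_end - region.start]
            assert p.sequence == brute_revcomp(window)
            assert reverse_complement(p.sequence) == window


class TestDesignPipeline:
    def test_composition(self, rng):
        region = _region(random_sequence(150, rng))
        cfg = DesignConfig(top_n=20, gap=50)
        ps = design_probe_set([[region]], cfg)
        assert len(ps) == 2
        assert ps.report["n_retained"] == 1

    def test_identical_top_regions_dedup_before_tiling(self, rng):
        seq = random_sequence(300, rng)
        r1 = _region(seq, sample_id="s1")
        r2 = _region(seq, sample_id="s2")
        ps = design_probe_set([[r1], [r2]], DesignConfig(top_n=5, gap=25))
        assert ps.report["n_pooled"] == 2
        assert ps.report["n_retained"] == 1
        assert len(ps) == len(tile_probes(r1, 50, 25))

    def test_empty_input(self):
        ps = design_probe_set([[]], DesignConfig())
        assert len(ps) == 0

    def test_staged_oracle_composition(self, rng):
        per_sample = []
        for s in range(3):
            sample = [
                _region(
                    random_sequence(int(rng.integers(100, 400)), rng),
                    start=i * 500,
                    ref_id=f"ref{i}",
                    median=float(rng.integers(500, 3000)),
                    sample_id=f"s{s}",
                )
                for i in range(6)
            ]
            per_sample.append(sample)
        cfg = DesignConfig(top_n=4, gap=30, seed=17)
        ps = design_probe_set(per_sample, cfg)
        # run the four stages independently
        selected = [
            sorted(s, key=lambda r: (-r.median_depth, r.ref_id, r.start))[:4] for s in per_sample
        ]
        pooled = [r for s in selected for r in s]
        retained = deduplicate_regions(pooled, 0.80, seed=17)
        expected = sum(len(brute_tiling(len(r), 50, 30)) for r in retained)
        assert len(ps) == expected


class TestDesignMatrix:
    def _per_sample(self, rng, n_samples=3, n_regions=30):
        out = []
        for s in range(n_samples):
            out.append(
                [
                    _region(
                        random_sequence(int(rng.integers(100, 500)), rng),
                        start=i * 600,
                        ref_id=f"ref{i}",
                        median=float(rng.integers(501, 5000)),
                        sample_id=f"s{s}",
                    )
                    for i in range(n_regions)
                ]
            )
        return out

    def test_gap_monotonicity_single_region(self, rng):
        region = _region(random_sequence(500, rng))
        counts = design_matrix([[region]], [1], [25, 30, 35, 40, 45, 50]).loc[1]
        assert (counts.diff().dropna() <= 0).all()

    def test_top_n_monotonicity(self, rng):
        per_sample = self._per_sample(rng)
        table = design_matrix(per_sample, [20, 50], [25, 50], DesignConfig(seed=5))
        for gap in (25, 50):
            assert table.loc[50, gap] >= table.loc[20, gap]

    def test_cells_equal_independent_runs(self, rng):
        per_sample = self._per_sample(rng, n_samples=2, n_regions=8)
        cfg = DesignConfig(seed=23)
        table = design_matrix(per_sample, [3, 6], [25, 40], cfg)
        for top_n in (3, 6):
            for gap in (25, 40):
                from dataclasses import replace

                ps = design_probe_set(per_sample, replace(cfg, top_n=top_n, gap=gap))
                assert table.loc[top_n, gap] == len(ps)

    def test_pool_naming(self):
        assert pool_name(50, 50) == "5050"
        assert pool_name(20, 25) == "2025"


class TestDesignConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DesignConfig(identity_threshold=0.0)
        with pytest.raises(ValueError):
            DesignConfig(top_n=0)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("top_n: 30\ngap: 45\nseed: 99\n")
        cfg = DesignConfig.from_yaml(path)
        assert (cfg.top_n, cfg.gap, cfg.seed) == (30, 45, 99)
        with pytest.raises(ValueError):
            path.write_text("bogus_key: 1\n")
            DesignConfig.from_yaml(path)
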