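import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regdiver import pipeline as pl
from regdiver import synth


def make_matrix(calls: dict[int, dict[str, str]], refs: dict[int, str],
                runs: list[str]) -> pl.VariantMatrix:
    positions = sorted(refs)
    df = pd.DataFrame(
        {r: [calls.get(p, {}).get(r, refs[p]) for p in positions]
         for r in runs},
        index=pd.Index(positions, name="pos"))
    return pl.VariantMatrix(calls=df, ref=pd.Series(
        [refs[p] for p in positions], index=df.index))


class TestCleanSnpMatrix:
    RUNS = [f"r{i:03d}" for i in range(100)]

    def test_position_ambiguous_in_11_percent_dropped(self):
        calls = {5: {r: "N" for r in self.RUNS[:11]}}
        calls[5][self.RUNS[50]] = "G"  # otherwise variant
        m = make_matrix(calls, {5: "A"}, self.RUNS)
        out = pl.clean_snp_matrix(m, [(0, 100)])
        assert out.is_empty()

    def test_modal_imputation_keeps_variant_position(self):
        calls = {5: {self.RUNS[0]: "G", **{r: "N" for r in self.RUNS[1:5]}}}
        m = make_matrix(calls, {5: "A"}, self.RUNS)
        out = pl.clean_snp_matrix(m, [(0, 100)])
        assert list(out.calls.index) == [5]
        # the 4 ambiguous calls imputed with the modal base A
        assert (out.calls.loc[5] == "N").sum() == 0
        assert (out.calls.loc[5] == "A").sum() == 99

    def test_position_invariant_after_imputation_dropped(self):
        calls = {5: {self.RUNS[0]: "N"}}
        m = make_matrix(calls, {5: "A"}, self.RUNS)
        with pytest.warns(UserWarning):
            out = pl.clean_snp_matrix(m, [(0, 100)])
        assert out.is_empty()

    def test_positions_outside_cds_removed(self):
        calls = {5: {self.RUNS[0]: "G"}, 250: {self.RUNS[0]: "T"}}
        m = make_matrix(calls, {5: "A", 250: "C"}, self.RUNS)
        out = pl.clean_snp_matrix(m, [(0, 100)])
        assert list(out.calls.index) == [5]

    def test_modal_tie_resolves_to_reference(self):
        runs = ["a", "b", "c"]
        calls = {5: {"a": "G", "b": "T", "c": "N"}}
        m = make_matrix(calls, {5: "T"}, runs)
        out = pl.clean_snp_matrix(m, [(0, 10)], max_ambiguous_frac=0.5)
        assert out.calls.at[5, "c"] == "T"

    def test_idempotent(self, rng):
        calls = {}
        refs = {}
        for p in range(40):
            refs[p] = "ACGT"[rng.integers(4)]
            row = {}
            for r in self.RUNS[:20]:
                u = rng.random()
                if u < 0.05:
                    row[r] = "N"
                elif u < 0.3:
                    row[r] = "ACGT"[rng.integers(4)]
            calls[p] = row
        m = make_matrix(calls, refs, self.RUNS[:20])
        once = pl.clean_snp_matrix(m, [(0, 30)])
        twice = pl.clean_snp_matrix(once, [(0, 30)])
        pd.testing.assert_frame_equal(once.calls, twice.calls)


class TestDetectGenes:
    def test_breadth_gate(self):
        present, _ = pl.detect_genes({"g1": (0.5, 500.0), "g2": (0.9, 50.0),
                                      "g3": (0.9, 48.0)})
        assert "g1" not in present

    def test_trimmed_gaussian_hand_case(self):
        prof = {f"g{i}": (1.0, d) for i, d in
                enumerate([10.0, 10.0, 10.0, 10.0, 100.0])}
        present, summ = pl.detect_genes(prof)
        assert present == set(prof)
        assert summ.x_bar == pytest.approx(28.0)
        assert summ.y_bar == pytest.approx(10.0)
        assert summ.s == pytest.approx(0.0)
        assert summ.threshold == pytest.approx(10.0)

    def test_all_zero_depth_none_present(self):
        present, _ = pl.detect_genes({"g1": (1.0, 0.0), "g2": (1.0, 0.0)})
        assert present == set()

    def test_single_gene_after_trim_warns_and_keeps(self):
        with pytest.warns(UserWarning):
            present, _ = pl.detect_genes({"g1": (1.0, 10.0)})
        assert present == {"g1"}

    def test_monotone_in_depth(self, rng):
        for _ in range(20):
            prof = {f"g{i}": (1.0, float(d))
                    for i, d in enumerate(rng.gamma(10, 5, size=30))}
            present, _ = pl.detect_genes(prof)
            g = rng.choice(sorted(prof))
            boosted = dict(prof)
            boosted[g] = (1.0, prof[g][1] * 3 + 1)
            present2, _ = pl.detect_genes(boosted)
            if g in present:
                assert g in present2

    def test_accuracy_on_synthetic_coverage(self):
        net = synth.generate_network(5, 50, seed=3)
        genome = synth.generate_genome(net, seed=4)
        absent = set(sorted(genome)[-6:])  # ~10% dropout
        present_truth = {"runA": set(genome) - absent}
        cov = synth.generate_coverage(genome, present_truth, mean_depth=50.0,
                                      duplicated={"tg0000"}, seed=5)
        called, _ = pl.detect_genes(cov.for_run("runA"))
        truth = present_truth["runA"]
        tp = len(called & truth)
        tn = len((set(genome) - called) & absent)
        assert tp / len(truth) >= 0.99
        assert tn / len(absent) >= 0.99


class TestFilterRuns:
    def test_boundary(self):
        dets = {"a": set(map(str, range(2999))),
                "b": set(map(str, range(3000))),
                "c": set()}
        assert pl.filter_runs(dets) == ["b"]


class TestSelectMarkerGenes:
    def test_percentile_band_hand_case(self):
        div = {f"g{i}": float(i) for i in range(1, 101)}
        core = {g: True for g in div}
        gapped = {g: False for g in div}
        markers = pl.select_marker_genes(div, core, gapped)
        assert markers == {f"g{i}" for i in range(76, 101)}

    def test_constant_diversity_gives_empty_set(self):
        div = {f"g{i}": 1.0 for i in range(10)}
        sel = pl.select_marker_genes(div, {g: True for g in div},
                                     {g: False for g in div})
        assert sel == set()

    def test_non_core_gene_excluded(self):
        div = {"g1": 100.0, "g2": 1.0, "g3": 2.0, "g4": 3.0}
        core = {"g1": False, "g2": True, "g3": True, "g4": True}
        gapped = {g: False for g in div}
        assert "g1" not in pl.select_marker_genes(div, core, gapped)

    def test_no_core_genes_errors(self):
        with pytest.raises(ValueError):
            pl.select_marker_genes({"g": 1.0}, {"g": False}, {"g": False})


class TestCodonDistance:
    def test_fraction_of_distinct_variant_codons(self):
        cvs = pl.CodonVariantSet("r1", {"g1": {0: "AAA", 3: "CCC", 7: "GGG"},
                                        "g2": {}})
        v = pl.codon_distance_vector(cvs, ["g1", "g2"],
                                     {"g1": 100, "g2": 50})
        assert v == pytest.approx([0.03, 0.0])

    def test_missing_marker_gene_errors_with_names(self):
        cvs = pl.CodonVariantSet("runX")
        with pytest.raises(ValueError, match="g1.*runX"):
            pl.codon_distance_vector(cvs, ["g1"], {"g1": 10}, detected=set())


class TestDecluster:
    def test_greedy_trace(self):
        vectors = {"a": np.array([0.0]), "b": np.array([0.05]),
                   "c": np.array([0.25])}
        assert pl.decluster(vectors) == ["a", "c"]

    def test_all_far_apart_all_kept(self):
        vectors = {f"r{i}": np.array([0.5 * i]) for i in range(5)}
        assert pl.decluster(vectors) == sorted(vectors)

    def test_identical_runs_keep_one(self):
        vectors = {f"r{i}": np.array([0.2, 0.3]) for i in range(4)}
        assert pl.decluster(vectors) == ["r0"]

    def test_pairwise_distances_exceed_threshold_posthoc(self, rng):
        for _ in range(10):
            vectors = {f"r{i:02d}": rng.uniform(0, 0.4, size=3)
                       for i in range(30)}
            kept = pl.decluster(vectors, min_dist=0.1)
            arrs = [vectors[r] for r in kept]
            for i in range(len(arrs)):
                for j in range(i + 1, len(arrs)):
                    assert np.linalg.norm(arrs[i] - arrs[j]) > 0.1
            # idempotence
            assert pl.decluster({r: vectors[r] for r in kept}) == kept

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(
        st.tuples(st.floats(0, 0.5, allow_nan=False),
                  st.floats(0, 0.5, allow_nan=False)),
        min_size=1, max_size=20))
    def test_contract_holds_for_arbitrary_point_sets(self, points):
        vectors = {f"r{i:02d}": np.array(p) for i, p in enumerate(points)}
        kept = pl.decluster(vectors, min_dist=0.1)
        assert kept  # the first run is always admitted
        arrs = [vectors[r] for r in kept]
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                assert np.linalg.norm(arrs[i] - arrs[j]) > 0.1


class TestCodonVariantsFromMatrix:
    def test_roundtrip_through_snp_matrix(self, cohort_setup):
        net, genome = cohort_setup
        cohort = synth.generate_isolates(net, genome, n_isolates=8,
                                         theta_tg=0.02, seed=9)
        matrix = synth.cohort_to_variant_matrix(cohort)
        intervals = [(g.start, g.end) for g in genome.values()]
        cleaned = pl.clean_snp_matrix(matrix, intervals)
        recovered = pl.codon_variants_from_matrix(cleaned, genome)
        for run, cvs in cohort.isolates.items():
            assert recovered[run].variants == cvs.variants
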