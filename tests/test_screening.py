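import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methoutlier.datamodel import MethylationMatrix, ProbeGeneMap, SampleAnnotation
from methoutlier.screening import (
    OutlierConfig,
    aggregate_probes,
    baseline_cutoff,
    call_outliers,
    compute_beta,
    compute_beta_matrix,
    permutation_null,
    rank_sum_score,
    screen_genes,
    select_candidates,
    score_gene,
)

from .oracles import rank_sum_oracle


class TestComputeBeta:
    def test_direct_ratio(self):
        assert compute_beta(25, 75) == pytest.approx(0.75)

    def test_zero_denominator_is_missing(self):
        assert math.isnan(compute_beta(0, 0))

    def test_fully_unmethylated(self):
        assert compute_beta(1000, 0) == 0.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(-1, 5)

    def test_matrix_form_matches_scalar(self):
        u = pd.DataFrame([[25.0, 0.0]], index=["p"], columns=["a", "b"])
        m = pd.DataFrame([[75.0, 0.0]], index=["p"], columns=["a", "b"])
        beta = compute_beta_matrix(u, m)
        assert beta.values.loc["p", "a"] == pytest.approx(0.75)
        assert math.isnan(beta.values.loc["p", "b"])


class TestAggregateProbes:
    def test_max_over_probes(self):
        probes = MethylationMatrix(
            pd.DataFrame(
                {"s1": [0.10, 0.40, 0.20]}, index=["p1", "p2", "p3"]
            ),
            level="probe",
        )
        pgmap = ProbeGeneMap({"p1": "g", "p2": "g", "p3": "g"})
        out = aggregate_probes(probes, pgmap)
        assert out.values.loc["g", "s1"] == pytest.approx(0.40)

    def test_max_over_non_missing(self):
        probes = MethylationMatrix(
            pd.DataFrame({"s1": [np.nan, 0.15]}, index=["p1", "p2"]),
            level="probe",
        )
        out = aggregate_probes(probes, ProbeGeneMap({"p1": "g", "p2": "g"}))
        assert out.values.loc["g", "s1"] == pytest.approx(0.15)

    def test_all_missing_stays_missing(self):
        probes = MethylationMatrix(
            pd.DataFrame({"s1": [np.nan, np.nan]}, index=["p1", "p2"]),
            level="probe",
        )
        out = aggregate_probes(probes, ProbeGeneMap({"p1": "g", "p2": "g"}))
        assert math.isnan(out.values.loc["g", "s1"])

    def test_row_count_equals_distinct_genes(self):
        # scaled-down structural analog of a many-probe platform collapsing
        # to fewer genes
        rng = np.random.default_rng(3)
        n_probes, n_genes = 275, 144
        mapping = {
            f"cg{i:05d}": f"gene{rng.integers(n_genes):04d}"
            for i in range(n_probes)
        }
        probes = MethylationMatrix(
            pd.DataFrame(
                rng.uniform(0, 1, size=(n_probes, 4)),
                index=list(mapping),
                columns=list("abcd"),
            ),
            level="probe",
        )
        out = aggregate_probes(probes, ProbeGeneMap(mapping))
        assert out.shape[0] == len(set(mapping.values()))

    def test_unmapped_probe_rejected(self):
        probes = MethylationMatrix(
            pd.DataFrame({"s1": [0.1]}, index=["p1"]), level="probe"
        )
        with pytest.raises(Exception):
            aggregate_probes(probes, ProbeGeneMap({}))


class TestBaselineCutoff:
    def test_floor_binds_when_iqr_zero(self):
        cfg = OutlierConfig(delta_min=0.1)
        c = baseline_cutoff([0.03] * 5, cfg, "right")
        assert c == pytest.approx(0.13)

    def test_hand_computed_quartiles(self):
        # type-7 quantiles: q75=0.3, IQR=0.2, median=0.2
        cfg = OutlierConfig(delta_min=0.1, fence_k=1.5)
        c = baseline_cutoff([0.0, 0.1, 0.2, 0.3, 0.4], cfg, "right")
        assert c == pytest.approx(max(0.3 + 1.5 * 0.2, 0.2 + 0.1)) == pytest.approx(0.6)

    def test_left_tail_mirror(self):
        cfg = OutlierConfig(delta_min=0.1)
        c = baseline_cutoff([0.9] * 5, cfg, "left")
        assert c == pytest.approx(0.8)

    def test_too_few_normals(self):
        with pytest.raises(Exception):
            baseline_cutoff([0.1, 0.2], OutlierConfig(), "right")


class TestCallOutliers:
    def test_right_tail_flags_extreme(self):
        vals = pd.Series([0.05, 0.08, 0.30], index=["a", "b", "c"])
        assert call_outliers(vals, 0.13, "right") == frozenset({"c"})

    def test_none_flagged(self):
        vals = pd.Series([0.05, 0.08], index=["a", "b"])
        assert call_outliers(vals, 0.13, "right") == frozenset()

    def test_boundary_is_strict(self):
        vals = pd.Series([0.13], index=["a"])
        assert call_outliers(vals, 0.13, "right") == frozenset()

    def test_missing_never_flagged(self):
        vals = pd.Series([np.nan, 0.5], index=["a", "b"])
        assert call_outliers(vals, 0.13, "right") == frozenset({"b"})


class TestRankSumScore:
    def test_two_largest_flagged(self):
        vals = pd.Series(
            [0.01, 0.02, 0.03, 0.04, 0.5, 0.6],
            index=["n1", "n2", "n3", "n4", "t1", "t2"],
        )
        s = rank_sum_score(vals, {"t1", "t2"})
        assert s == pytest.approx((5 + 6) / 6)

    def test_no_flags_scores_zero(self):
        vals = pd.Series([0.1, 0.2], index=["a", "b"])
        assert rank_sum_score(vals, set()) == 0.0

    def test_midranks_for_ties(self):
        vals = pd.Series(
            [0.01, 0.02, 0.03, 0.04, 0.6, 0.6],
            index=["n1", "n2", "n3", "n4", "t1", "t2"],
        )
        s = rank_sum_score(vals, {"t1", "t2"})
        assert s == pytest.approx(11 / 6)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=2,
            max_size=8,
        ),
        st.data(),
    )
    def test_matches_brute_force_oracle(self, values, data):
        flagged = data.draw(
            st.sets(st.integers(min_value=0, max_value=len(values) - 1))
        )
        vals = pd.Series(values, index=[f"s{i}" for i in range(len(values))])
        got = rank_sum_score(vals, {f"s{i}" for i in flagged})
        expect = rank_sum_oracle(values, flagged)
        assert got == pytest.approx(expect)

    def test_monotone_in_added_top_flags(self):
        rng = np.random.default_rng(11)
        vals = pd.Series(rng.uniform(size=10), index=[f"s{i}" for i in range(10)])
        order = vals.sort_values(ascending=False).index
        prev = 0.0
        flags: set = set()
        for sid in order:
            flags.add(sid)
            s = rank_sum_score(vals, flags)
            assert s >= prev
            prev = s


def _annotation(n_tumor, n_normal):
    ids = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ids,
                "patient_id": ids,
                "group": ["tumor"] * n_tumor + ["normal"] * n_normal,
                "specimen": ["tissue"] * len(ids),
            }
        )
    )


class TestScreenGenes:
    def test_constant_gene_scores_zero_and_ranks_last(self):
        ann = _annotation(4, 4)
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 0.05, size=(3, 8))
        vals[0, 0] = 0.9  # signal gene
        vals[2, :] = 0.2  # constant gene
        meth = MethylationMatrix(
            pd.DataFrame(vals, index=["g1", "g2", "g3"], columns=ann.sample_ids),
            level="gene",
        )
        res = screen_genes(meth, ann, OutlierConfig())
        by_gene = {r.gene_id: r for r in res}
        assert by_gene["g3"].score == 0.0
        assert res[-1].score == 0.0
        assert res[0].gene_id == "g1"

    def test_score_zero_iff_no_outliers(self, small_meth, small_annotation):
        for r in screen_genes(small_meth, small_annotation, OutlierConfig()):
            assert (r.score == 0.0) == (len(r.outlier_samples) == 0)
            assert r.outlier_samples <= set(small_annotation.samples_in_group("tumor"))

    def test_raising_delta_min_never_increases_score(self):
        ann = _annotation(6, 6)
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 0.4, size=(20, 12))
        meth = MethylationMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(20)],
                         columns=ann.sample_ids),
            level="gene",
        )
        lo = {r.gene_id: r.score
              for r in screen_genes(meth, ann, OutlierConfig(delta_min=0.05))}
        hi = {r.gene_id: r.score
              for r in screen_genes(meth, ann, OutlierConfig(delta_min=0.2))}
        for g in lo:
            assert hi[g] <= lo[g] + 1e-12

    def test_invariant_to_within_group_sample_order(self):
        ann = _annotation(5, 5)
        rng = np.random.default_rng(13)
        vals = rng.uniform(0, 0.8, size=(10, 10))
        meth = MethylationMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                         columns=ann.sample_ids),
            level="gene",
        )
        base = {r.gene_id: r.score for r in screen_genes(meth, ann, OutlierConfig())}
        cols = ann.sample_ids
        perm = cols[1:5][::-1] + [cols[0]] + cols[5:][::-1]
        meth2 = MethylationMatrix(meth.values.loc[:, perm], level="gene")
        permuted = {r.gene_id: r.score
                    for r in screen_genes(meth2, ann, OutlierConfig())}
        for g in base:
            assert permuted[g] == pytest.approx(base[g])

    def test_missing_group_rejected(self, small_meth):
        ann = _annotation(3, 0)
        ann.table["sample_id"] = ["T1", "T2", "T3"]
        with pytest.raises(Exception):
            screen_genes(small_meth, ann, OutlierConfig())

    def test_top_k_includes_ties(self):
        ann = _annotation(4, 4)
        vals = np.full((4, 8), 0.03)
        vals[0, 0] = 0.9
        vals[1, 0] = 0.9
        vals[2, 0] = 0.9
        meth = MethylationMatrix(
            pd.DataFrame(vals, index=["g1", "g2", "g3", "g4"],
                         columns=ann.sample_ids),
            level="gene",
        )
        res = screen_genes(meth, ann, OutlierConfig())
        sel = select_candidates(res, OutlierConfig(top_k=2))
        assert {r.gene_id for r in sel} == {"g1", "g2", "g3"}  # tied at k-th

    def test_score_cutoff_selection(self):
        ann = _annotation(4, 4)
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 0.05, size=(10, 8))
        vals[:3, 0] = 0.9
        meth = MethylationMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                         columns=ann.sample_ids),
            level="gene",
        )
        res = screen_genes(meth, ann, OutlierConfig())
        kth = sorted((r.score for r in res), reverse=True)[2]
        sel = select_candidates(res, OutlierConfig(score_cutoff=kth))
        assert len(sel) == 3


class TestPermutationNull:
    def test_determinism(self):
        vals = pd.Series(
            np.r_[np.random.default_rng(1).uniform(0, 0.05, 8), [0.6, 0.7]],
            index=[f"s{i}" for i in range(10)],
        )
        cfg = OutlierConfig(n_permutations=50, seed=42)
        tum = [f"s{i}" for i in range(5)] + ["s8", "s9"]
        norm = [f"s{i}" for i in range(5, 8)]
        p1 = permutation_null(vals, tum, norm, cfg)
        p2 = permutation_null(vals, tum, norm, cfg)
        assert p1 == p2

    def test_score_zero_gives_p_one(self):
        vals = pd.Series(np.full(10, 0.03), index=[f"s{i}" for i in range(10)])
        cfg = OutlierConfig(n_permutations=20, seed=0)
        p = permutation_null(vals, [f"s{i}" for i in range(5)],
                             [f"s{i}" for i in range(5, 10)], cfg)
        assert p == 1.0

    def test_zero_permutations_rejected(self):
        vals = pd.Series(np.arange(6) / 10, index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError):
            permutation_null(vals, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                             OutlierConfig(n_permutations=0))

    def test_null_p_uniformity(self):
        # identical groups => p approximately uniform across null genes
        from scipy.stats import kstest

        rng = np.random.default_rng(77)
        # continuous-ish score regime: no floor, cutoff at the normals' q75
        cfg = OutlierConfig(n_permutations=200, seed=1,
                            delta_min=0.0, fence_k=0.0, tail="right")
        ids = [f"s{i}" for i in range(20)]
        tum, norm = ids[:10], ids[10:]
        pvals = []
        gen = np.random.default_rng(99)
        for _ in range(200):
            vals = pd.Series(rng.uniform(0, 1, 20), index=ids)
            pvals.append(permutation_null(vals, tum, norm, cfg, rng=gen))
        stat = kstest(pvals, "uniform").pvalue
        assert stat > 0.01
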