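"""LTR dedup, anchored profiles and the rank-sum test, versus brute force."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from ervscape import (
    AnchorSet,
    SimulationConfig,
    average_profile,
    build_profile_matrix,
    dedup_ltrs,
    generate_repeat_annotation,
    ltr_differential_test,
    wilcoxon_rank_sum,
)
from ervscape.annotation import RepeatAnnotation
from ervscape.synth import default_family_ltr_map


def _annotation(rows, lengths=None):
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "locus_id", "score", "strand", "family", "integration_id"],
    )
    return RepeatAnnotation(df, genome_lengths=lengths or {})


FAM_MAP = {"IAP": ["IAP_LTR"]}


class TestDedup:
    def test_full_length_keeps_five_prime_ltr_only(self):
        ann = _annotation(
            [
                ("c1", 100, 200, "a", 0, "+", "IAP_LTR", "i1"),
                ("c1", 200, 700, "b", 0, "+", "IAP_int", "i1"),
                ("c1", 700, 800, "c", 0, "+", "IAP_LTR", "i1"),
            ]
        )
        anchors = dedup_ltrs(ann, FAM_MAP)
        assert len(anchors) == 1
        assert anchors.anchors.position.iloc[0] == 100  # 5' boundary on + strand

    def test_minus_strand_five_prime_is_rightmost(self):
        ann = _annotation(
            [
                ("c1", 100, 200, "a", 0, "-", "IAP_LTR", "i1"),
                ("c1", 200, 700, "b", 0, "-", "IAP_int", "i1"),
                ("c1", 700, 800, "c", 0, "-", "IAP_LTR", "i1"),
            ]
        )
        anchors = dedup_ltrs(ann, FAM_MAP)
        # on - strand the 5' LTR is the rightmost one; anchor at its end
        assert anchors.anchors.position.iloc[0] == 800

    def test_orphan_retained(self):
        ann = _annotation([("c1", 100, 200, "a", 0, "+", "IAP_LTR", "solo1")])
        anchors = dedup_ltrs(ann, FAM_MAP)
        assert len(anchors) == 1 and anchors.anchors.family.iloc[0] == "IAP"

    def test_anchor_counting(self):
        cfg = SimulationConfig(
            seed=5, n_families=3, loci_per_family=20, genome_length=3_000_000,
            orphan_fraction=0.4,
            enrichment_factors={"d": {f"fam{i:02d}": 1.0 for i in range(1, 4)}},
            library_sizes={"d": 10**6},
        )
        ann = generate_repeat_annotation(cfg)
        anchors = dedup_ltrs(ann, default_family_ltr_map(cfg))
        assert len(anchors) == 3 * 20  # one anchor per integration, orphan or full-length

    def test_matches_per_integration_rule_oracle(self):
        # ~1,000 random loci across orphan and full-length integrations
        cfg = SimulationConfig(
            seed=6, n_families=4, loci_per_family=110, genome_length=12_000_000,
            orphan_fraction=0.35,
            enrichment_factors={"d": {f"fam{i:02d}": 1.0 for i in range(1, 5)}},
            library_sizes={"d": 10**6},
        )
        ann = generate_repeat_annotation(cfg)
        assert len(ann) >= 1000
        anchors = dedup_ltrs(ann, default_family_ltr_map(cfg))

        expected = {}
        for intg, grp in ann.df.groupby("integration_id"):
            ltrs = grp[grp.family.str.endswith("_LTR")].sort_values("start")
            keep = ltrs.iloc[0] if ltrs.strand.iloc[0] == "+" else ltrs.iloc[-1]
            expected[intg] = keep.start if keep.strand == "+" else keep.end
        got = dict(zip(anchors.anchors.integration_id, anchors.anchors.position))
        assert got == expected

    def test_two_five_prime_ltrs_is_error(self):
        ann = _annotation(
            [
                ("c1", 100, 200, "a", 0, "+", "IAP_LTR", "i1"),
                ("c1", 250, 350, "b", 0, "+", "IAP_LTR", "i1"),
                ("c1", 400, 900, "c", 0, "+", "IAP_int", "i1"),
                ("c1", 950, 1050, "d", 0, "+", "IAP_LTR", "i1"),
            ]
        )
        with pytest.raises(Exception, match="i1"):
            dedup_ltrs(ann, FAM_MAP)


def _uniform_anchorset(rows, up=100, down=200, width=10):
    return AnchorSet(pd.DataFrame(rows), window_up=up, window_down=down, bin_size=width)


class TestProfileMatrix:
    def test_column_count(self):
        rows = [{"chrom": "c1", "position": 5000, "strand": "+", "family": "f",
                 "integration_id": "i1", "start": 5000, "end": 5100}]
        anchors = _uniform_anchorset(rows, up=1500, down=8000, width=50)
        cov = {"c1": np.ones(20000)}
        m = build_profile_matrix(cov, anchors)
        assert m.values.shape == (1, 190)

    def test_uniform_coverage_constant(self):
        rows = [
            {"chrom": "c1", "position": 2000, "strand": s, "family": "f",
             "integration_id": f"i{k}", "start": 2000, "end": 2100}
            for k, s in enumerate("+-")
        ]
        cov = {"c1": np.full(10000, 3.5)}
        m = build_profile_matrix(cov, _uniform_anchorset(rows))
        assert np.allclose(m.values, 3.5, atol=1e-12) and not m.mask.any()

    def test_equals_per_base_brute_force(self, rng):
        cov = {"c1": rng.random(100_000)}
        rows = [
            {"chrom": "c1", "position": int(p), "strand": s, "family": "f",
             "integration_id": f"i{k}", "start": int(p), "end": int(p) + 50}
            for k, (p, s) in enumerate(zip(rng.integers(500, 99_000, 8), "+-+-+-+-"))
        ]
        up, down, width = 100, 200, 10
        anchors = _uniform_anchorset(rows, up, down, width)
        m = build_profile_matrix(cov, anchors, sort_rows=False)
        for i, a in enumerate(rows):
            for b in range((up + down) // width):
                vals = []
                for j in range(width):
                    x = -up + b * width + j
                    pos = a["position"] + x if a["strand"] == "+" else a["position"] - 1 - x
                    if 0 <= pos < 100_000:
                        vals.append(cov["c1"][pos])
                assert m.values[i, b] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_out_of_genome_bins_masked(self):
        rows = [{"chrom": "c1", "position": 30, "strand": "+", "family": "f",
                 "integration_id": "i1", "start": 30, "end": 60}]
        m = build_profile_matrix({"c1": np.ones(1000)}, _uniform_anchorset(rows))
        assert m.mask[0, :7].all()  # bins fully left of the chromosome start
        assert not m.mask[0, 10:].any()

    def test_missing_chromosome_is_error(self):
        rows = [{"chrom": "cX", "position": 500, "strand": "+", "family": "f",
                 "integration_id": "i1", "start": 500, "end": 550}]
        with pytest.raises(KeyError, match="cX"):
            build_profile_matrix({"c1": np.ones(1000)}, _uniform_anchorset(rows))

    def test_strand_symmetry_under_genome_flip(self, rng):
        G = 50_000
        cov = {"c1": rng.random(G)}
        cfg = SimulationConfig(
            seed=8, n_families=2, loci_per_family=10, genome_length=G,
            orphan_fraction=0.5, internal_length=800, ltr_length=120,
            enrichment_factors={"d": {"fam01": 1.0, "fam02": 1.0}},
            library_sizes={"d": 10**6},
        )
        ann = generate_repeat_annotation(cfg)
        fam_map = default_family_ltr_map(cfg)
        flipped_df = ann.df.copy()
        flipped_df["start"], flipped_df["end"] = G - ann.df.end, G - ann.df.start
        flipped_df["strand"] = ann.df.strand.map({"+": "-", "-": "+"})
        flipped = RepeatAnnotation(flipped_df.rename(columns={"chrom": "chrom"}), {"chrS": G})
        cov_f = {"chrS": cov["c1"][::-1].copy()}
        cov_o = {"chrS": cov["c1"]}

        a_o = dedup_ltrs(ann, fam_map, window_up=100, window_down=300, bin_size=20)
        a_f = dedup_ltrs(flipped, fam_map, window_up=100, window_down=300, bin_size=20)
        p_o = average_profile(build_profile_matrix(cov_o, a_o))
        p_f = average_profile(build_profile_matrix(cov_f, a_f))
        assert np.allclose(p_o["mean"], p_f["mean"], atol=1e-12, equal_nan=True)


class TestAverageProfile:
    def _matrix(self, values, mask=None):
        from ervscape.ltr import ProfileMatrix

        values = np.asarray(values, dtype=float)
        return ProfileMatrix(
            values=values,
            mask=np.zeros_like(values, bool) if mask is None else np.asarray(mask, bool),
            anchor_ids=[f"i{k}" for k in range(values.shape[0])],
            bin_starts=np.arange(values.shape[1]),
            bin_size=1,
        )

    def test_single_row_is_identity(self):
        prof = average_profile(self._matrix([[1.0, 2.0, 3.0]]))
        assert np.allclose(prof["mean"], [1, 2, 3])

    def test_two_rows_mean(self):
        prof = average_profile(self._matrix([[1.0, 2.0], [3.0, 6.0]]))
        assert np.allclose(prof["mean"], [2.0, 4.0])

    def test_row_permutation_invariance(self, rng):
        vals = rng.random((6, 10))
        p1 = average_profile(self._matrix(vals))
        p2 = average_profile(self._matrix(vals[::-1]))
        assert np.allclose(p1["mean"], p2["mean"], atol=1e-15)

    def test_fully_masked_column_flagged_missing(self):
        vals = [[1.0, np.nan], [2.0, np.nan]]
        mask = [[False, True], [False, True]]
        prof = average_profile(self._matrix(vals, mask))
        assert np.isnan(prof["mean"].iloc[1]) and prof["n"].iloc[1] == 0


class TestDifferentialTest:
    def test_worked_example_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_condition_is_error(self):
        a = pd.DataFrame({"family": ["f1"], "count": [1.0]})
        b = pd.DataFrame({"family": ["f2"], "count": [2.0]})
        with pytest.raises(ValueError, match="zero anchors"):
            ltr_differential_test(a, b)

    def test_bh_step_up_arithmetic(self):
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03], atol=1e-12)

    def test_planted_reduction_detected(self, rng):
        fams = np.repeat([f"f{i}" for i in range(10)], 30)
        a = pd.DataFrame({"family": fams, "count": rng.poisson(50, fams.size).astype(float)})
        counts_b = rng.poisson(50, fams.size).astype(float)
        counts_b[fams == "f0"] = rng.poisson(12.5, 30)
        b = pd.DataFrame({"family": fams, "count": counts_b})
        res = ltr_differential_test(a, b).set_index("family")
        assert res.loc["f0", "p_adj"] < 0.05
        assert (res.drop("f0").p_adj > 0.05).all()
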