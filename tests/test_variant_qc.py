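"""Variant filters, rare-variant rescue and sample exclusion rules."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cypmeta.star_alleles import VariantSite
from cypmeta.variant_qc import (
    QCThresholds,
    SampleQCRecord,
    VariantRecord,
    exclude_samples,
    filter_variants,
    qc_variants,
    rescue_rare_variants,
)


def _var(i, maf, info, star=False, genotyped=False, review=None):
    return VariantRecord(
        site=VariantSite(f"v{i}", "22", 42_000_000 + i, "A", "G"),
        maf=maf, info_score=info, genotyped=genotyped,
        is_star_defining=star, cluster_review_pass=review,
    )


class TestFilterVariants:
    def test_rare_common_variant_excluded_for_maf(self):
        retained, rescue, log = filter_variants([_var(1, 0.005, 0.9)])
        assert retained == [] and rescue == []
        assert log.rows[0]["reason"] == "maf"

    def test_common_good_variant_retained(self):
        retained, _, _ = filter_variants([_var(1, 0.30, 0.95)])
        assert len(retained) == 1

    def test_low_info_excluded_with_info_reason(self):
        _, _, log = filter_variants([_var(1, 0.30, 0.2)])
        assert log.rows[0]["reason"] == "info"

    def test_star_defining_failures_divert_to_rescue(self):
        _, rescue, log = filter_variants([_var(1, 0.002, 0.7, star=True)])
        assert len(rescue) == 1 and log.rows == []

    def test_partition_and_order_invariance(self, rng):
        variants = [
            _var(i, rng.uniform(0, 0.5), rng.uniform(0, 1)) for i in range(100)
        ]
        retained, rescue, log = filter_variants(variants)
        assert len(retained) + len(rescue) + len(log.rows) == 100
        shuffled = list(variants)
        rng.shuffle(shuffled)
        retained2, _, _ = filter_variants(shuffled)
        assert {v.site.id for v in retained} == {v.site.id for v in retained2}

    @settings(deadline=None, derandomize=True)
    @given(
        mafs=st.lists(st.floats(0, 0.5), min_size=1, max_size=30),
        maf_min=st.floats(0.0, 0.2),
        bump=st.floats(0.0, 0.2),
    )
    def test_raising_thresholds_never_grows_retained_set(self, mafs, maf_min, bump):
        variants = [_var(i, m, 0.9) for i, m in enumerate(mafs)]
        lo = QCThresholds(maf_min=maf_min)
        hi = QCThresholds(maf_min=min(maf_min + bump, 1.0))
        kept_lo, _, _ = filter_variants(variants, lo)
        kept_hi, _, _ = filter_variants(variants, hi)
        assert {v.site.id for v in kept_hi} <= {v.site.id for v in kept_lo}


class TestRescue:
    def test_imputed_above_stricter_threshold_rescued(self):
        kept, _ = rescue_rare_variants([_var(1, 0.002, 0.65, star=True)])
        assert len(kept) == 1

    def test_imputed_below_stricter_threshold_dropped(self):
        kept, log = rescue_rare_variants([_var(1, 0.002, 0.55, star=True)])
        assert kept == [] and log.rows[0]["reason"] == "rescue_info"

    def test_genotyped_requires_cluster_review(self):
        fail = _var(1, 0.002, 0.9, star=True, genotyped=True, review=False)
        ok = _var(2, 0.002, 0.9, star=True, genotyped=True, review=True)
        kept, log = rescue_rare_variants([fail, ok])
        assert [v.site.id for v in kept] == ["v2"]
        assert log.rows[0]["reason"] == "cluster_review"

    def test_non_star_candidate_rejected(self):
        with pytest.raises(ValueError, match="star-defining"):
            rescue_rare_variants([_var(1, 0.002, 0.9)])

    def test_combined_qc_keeps_common_plus_rescued(self):
        variants = [
            _var(1, 0.3, 0.9),                      # common, good
            _var(2, 0.002, 0.7, star=True),         # rare star, rescued
            _var(3, 0.002, 0.4, star=True),         # rare star, fails rescue
            _var(4, 0.002, 0.9),                    # rare non-star, gone
        ]
        kept, log = qc_variants(variants)
        assert {v.site.id for v in kept} == {"v1", "v2"}
        assert log.counts() == {"maf": 1, "rescue_info": 1}


class TestSampleExclusion:
    def test_high_missingness_removed_first(self):
        kept, log = exclude_samples(
            [SampleQCRecord("a", missingness=0.12, sex_mismatch=True)], []
        )
        assert kept == [] and log.rows[0]["reason"] == "missingness"

    def test_kinship_pair_loses_exactly_one_member(self):
        samples = [SampleQCRecord("a"), SampleQCRecord("b")]
        kept, log = exclude_samples(samples, [("a", "b", 0.09)])
        assert len(kept) == 1 and len(log.rows) == 1
        assert log.rows[0]["reason"] == "kinship_pair"

    def test_borderline_kinship_keeps_both(self):
        samples = [SampleQCRecord("a"), SampleQCRecord("b")]
        kept, _ = exclude_samples(samples, [("a", "b", 0.083)])  # not strictly above
        assert sorted(kept) == ["a", "b"]

    def test_chain_removes_shared_middle_only(self):
        """Oracle: of all ways to break the A-B, B-C chain, removing B alone
        keeps two samples; any other choice keeps fewer."""
        samples = [SampleQCRecord(s) for s in "abc"]
        pairs = [("a", "b", 0.1), ("b", "c", 0.1)]
        best = 0
        for removal in itertools.chain.from_iterable(
            itertools.combinations("abc", k) for k in range(4)
        ):
            left = set("abc") - set(removal)
            if all(not ({x, y} <= left) for x, y, _ in pairs):
                best = max(best, len(left))
        kept, _ = exclude_samples(samples, pairs)
        assert len(kept) == best == 2
        assert sorted(kept) == ["a", "c"]

    def test_unknown_sample_in_pair_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            exclude_samples([SampleQCRecord("a")], [("a", "zz", 0.2)])

    @settings(deadline=None, derandomize=True)
    @given(st.data())
    def test_no_residual_pair_exceeds_threshold(self, data):
        n = data.draw(st.integers(2, 12))
        ids = [f"s{i}" for i in range(n)]
        samples = [SampleQCRecord(s) for s in ids]
        pairs = data.draw(
            st.lists(
                st.tuples(
                    st.sampled_from(ids), st.sampled_from(ids), st.floats(0, 0.5)
                ),
                max_size=20,
            )
        )
        pairs = [(a, b, k) for a, b, k in pairs if a != b]
        kept, log = exclude_samples(samples, pairs)
        kept_set = set(kept)
        for a, b, k in pairs:
            if k > 0.083:
                assert not {a, b} <= kept_set
        # partition: every sample is kept or logged exactly once
        assert len(kept) + len({r["id"] for r in log.rows}) == n
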