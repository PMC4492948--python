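"""Genotype resolution from block records and eVCF assembly."""

import numpy as np
import pytest

from evcfkit.errors import OverlapError
from evcfkit.evcf_builder import (
    CallSummary,
    ConfidencePolicy,
    build_evcf,
    index_gvcf,
    resolve_genotype,
    resolve_genotype_bruteforce,
)
from evcfkit.genotypes import CallClass, CallSource
from evcfkit.synthetic_data import SimulationConfig, simulate_dataset
from evcfkit.vcf_io import GvcfRecord, RecordKind

from conftest import make_site


def block(pos, end, gqx=50.0, min_dp=30, contig="chr1", ref="A", filt=("PASS",)):
    return GvcfRecord(
        contig=contig, pos=pos, ref=ref, kind=RecordKind.BLOCK, filter=filt,
        end=end, gt=(0, 0), gqx=gqx, dp=min_dp + 2, min_dp=min_dp,
    )


def variant(pos, ref="A", alts=("G",), gt=(0, 1), contig="chr1", gqx=90.0):
    return GvcfRecord(
        contig=contig, pos=pos, ref=ref, kind=RecordKind.VARIANT, alts=alts,
        qual=gqx, filter=("PASS",), gt=gt, gqx=gqx, dp=35,
    )


class TestConfidencePolicy:
    def test_missing_gqx_fails_any_finite_threshold(self):
        b = block(100, 199)
        b.gqx = None
        assert not ConfidencePolicy(min_gqx=0).block_passes(b)

    def test_non_pass_block_fails_unless_waived(self):
        b = block(100, 199, filt=("LowGQX",))
        assert not ConfidencePolicy().block_passes(b)
        assert ConfidencePolicy(require_pass=False).block_passes(b)

    def test_dp_fallback_when_min_dp_missing(self):
        b = block(100, 199)
        b.min_dp = None
        b.dp = 4
        assert not ConfidencePolicy(min_dp=5).block_passes(b)
        b.dp = 5
        assert ConfidencePolicy(min_dp=5).block_passes(b)

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ConfidencePolicy(min_gqx=-1)


class TestGvcfIndex:
    def test_point_query_hits_containing_block(self):
        idx = index_gvcf([block(100, 199)])
        assert [r.pos for r in idx.query("chr1", 150)] == [100]

    def test_point_query_hits_variant(self):
        idx = index_gvcf([variant(1500)])
        assert [r.pos for r in idx.query("chr1", 1500)] == [1500]

    def test_uncovered_position_returns_empty(self):
        idx = index_gvcf([block(100, 199)])
        assert idx.query("chr1", 5000) == []
        assert idx.query("chr9", 150) == []

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(OverlapError):
            index_gvcf([block(100, 199), block(150, 250)])

    def test_abutting_blocks_accepted(self):
        idx = index_gvcf([block(100, 199), block(200, 299)])
        assert len(idx.query("chr1", 200)) == 1


class TestResolveGenotype:
    def test_site_inside_passing_block_is_homref(self):
        idx = index_gvcf([block(150, 250)])
        call = resolve_genotype(make_site(200, "A"), idx)
        assert call.call_class is CallClass.HOM_REF and call.source is CallSource.BLOCK
        assert call.gqx == 50 and call.dp == 30

    def test_low_gqx_block_gives_no_call(self):
        idx = index_gvcf([block(150, 250, gqx=10.0)])
        call = resolve_genotype(make_site(200, "A"), idx)
        assert call.call_class is CallClass.NO_CALL and call.source is CallSource.NONE

    def test_variant_record_supplies_genotype(self):
        idx = index_gvcf([variant(1500, "A", ("G",), (0, 1))])
        call = resolve_genotype(make_site(1500, "A", ("G",)), idx)
        assert call.call_class is CallClass.HET
        assert call.alleles == ("A", "G") and call.source is CallSource.VARIANT_RECORD

    @pytest.mark.parametrize(
        "gt, expected",
        [
            ((0, 0), CallClass.HOM_REF),
            ((0, 1), CallClass.HET),
            ((1, 1), CallClass.HOM_ALT),
            ((1, 2), CallClass.HET_ALT),
        ],
    )
    def test_gt_indices_to_class(self, gt, expected):
        idx = index_gvcf([variant(1500, "A", ("G", "T"), gt)])
        call = resolve_genotype(make_site(1500, "A", ("G", "T")), idx)
        assert call.call_class is expected

    def test_multibase_ref_span_must_be_fully_covered(self):
        # site spans 248..250 but the passing block ends at 249
        idx = index_gvcf([block(150, 249)])
        call = resolve_genotype(make_site(248, "ATG"), idx)
        assert call.call_class is CallClass.NO_CALL
        # brute-force per-base scan agrees
        oracle = resolve_genotype_bruteforce(make_site(248, "ATG"), [block(150, 249)])
        assert oracle.call_class is CallClass.NO_CALL

    def test_multibase_span_across_abutting_blocks_is_homref(self):
        idx = index_gvcf([block(150, 249, gqx=60), block(250, 300, gqx=40)])
        call = resolve_genotype(make_site(248, "ATG"), idx)
        assert call.call_class is CallClass.HOM_REF
        assert call.gqx == 40  # minimum over covering blocks

    def test_ref_mismatch_with_variant_flags_conflict(self):
        idx = index_gvcf([variant(1500, "C", ("G",))])
        call = resolve_genotype(make_site(1500, "A", ("G",)), idx)
        assert call.call_class is CallClass.NO_CALL and call.conflict

    def test_threshold_monotonicity(self):
        """Raising gqx/depth floors never turns NO_CALL into a call and never
        touches variant-record genotypes; the hom-ref count is non-increasing."""
        ds = simulate_dataset(
            SimulationConfig(genome_length=10_000, n_sites=150, nocall_fraction=0.1, seed=3)
        )
        idx = index_gvcf(ds.gvcf)
        policies = [
            ConfidencePolicy(min_gqx=g, min_dp=d)
            for g in (0, 20, 40, 80)
            for d in (0, 5, 25)
        ]
        policies.sort(key=lambda p: (p.min_gqx, p.min_dp))
        prev_calls = None
        for policy in policies:
            calls = {s.key: resolve_genotype(s, idx, policy) for s in ds.truth.sites}
            if prev_calls is not None:
                for key, call in calls.items():
                    prev = prev_calls[key]
                    if prev.call_class is CallClass.NO_CALL:
                        # same gqx ordering: stricter policy keeps it uncalled
                        if policy.min_gqx >= prev_policy.min_gqx and policy.min_dp >= prev_policy.min_dp:
                            assert call.call_class is CallClass.NO_CALL
                    if prev.source is CallSource.VARIANT_RECORD:
                        assert call.call_class is prev.call_class
            prev_calls, prev_policy = calls, policy
        homref_counts = [
            sum(
                1
                for s in ds.truth.sites
                if resolve_genotype(s, idx, ConfidencePolicy(min_gqx=g)).call_class
                is CallClass.HOM_REF
            )
            for g in (0, 20, 50, 99)
        ]
        assert homref_counts == sorted(homref_counts, reverse=True)


class TestBuildEvcf:
    def test_empty_catalog_gives_variant_records_only(self, small_dataset):
        records, summary, _ = build_evcf(small_dataset.gvcf, [])
        n_variants = sum(
            1 for r in small_dataset.gvcf if r.kind is RecordKind.VARIANT
        )
        assert len(records) == n_variants == summary.n_variant_records_passthrough
        assert summary.n_sites == 0

    def test_sites_in_pass_blocks_add_homref_records(self):
        gvcf = [block(1, 1000)]
        catalog = [make_site(100), make_site(200, "C", ("T",)), make_site(300, "G", ("A",))]
        records, summary, _ = build_evcf(gvcf, catalog)
        assert summary.n_hom_ref == 3 and len(records) == 3
        assert all(r.alts == () and r.gt == (0, 0) for r in records)

    def test_summary_conservation(self, small_dataset):
        _, summary, _ = build_evcf(small_dataset.gvcf, small_dataset.truth.sites)
        assert summary.n_sites == len(small_dataset.truth.sites) == summary.class_total

    def test_record_count_accounting(self, small_dataset):
        records, summary, _ = build_evcf(small_dataset.gvcf, small_dataset.truth.sites)
        assert len(records) == (
            summary.n_variant_records_passthrough + summary.n_catalog_records_emitted
        )

    def test_skip_nocalls_drops_only_nocall_records(self, small_dataset):
        with_nc, s1, _ = build_evcf(
            small_dataset.gvcf, small_dataset.truth.sites, emit_nocalls=True
        )
        without_nc, s2, _ = build_evcf(
            small_dataset.gvcf, small_dataset.truth.sites, emit_nocalls=False
        )
        assert s1.n_no_call == s2.n_no_call  # accounting unchanged
        dropped = len(with_nc) - len(without_nc)
        assert dropped == s1.n_no_call > 0

    def test_catalog_ref_conflict_emitted_as_flagged_nocall(self):
        gvcf = [variant(500, "C", ("T",))]
        records, summary, _ = build_evcf(gvcf, [make_site(500, "A", ("G",))])
        assert summary.conflicts and summary.n_no_call == 1
        flagged = [r for r in records if r.info.get("conflict")]
        assert len(flagged) == 1 and flagged[0].gt is None

    def test_output_sorted_by_contig_then_position(self, small_dataset):
        records, _, _ = build_evcf(small_dataset.gvcf, small_dataset.truth.sites)
        positions = [r.pos for r in records]
        assert positions == sorted(positions)

    def test_indexed_resolution_matches_bruteforce(self, small_dataset):
        idx = index_gvcf(small_dataset.gvcf)
        for site in small_dataset.truth.sites[:200]:
            fast = resolve_genotype(site, idx)
            slow = resolve_genotype_bruteforce(site, small_dataset.gvcf)
            assert fast.call_class is slow.call_class
            assert fast.alleles == slow.alleles
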