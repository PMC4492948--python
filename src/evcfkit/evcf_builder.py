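"""Resolve genotypes at catalog sites from a gVCF and assemble the eVCF.

A variant-only VCF cannot distinguish "homozygous reference" from "no
confident call" — both are simply absent.  The gVCF closes that gap by
covering non-variant stretches with block records carrying confidence
summaries (GQX, MIN_DP).  This module turns that evidence into an explicit
five-way genotype at every catalog site:

* a variant record at the site supplies the genotype directly (its FILTER is
  passed through; the confidence policy is not re-applied to the caller's
  variant calls);
* otherwise, if every base of the site's REF span lies inside non-variant
  blocks that pass the policy, the site is homozygous reference;
* otherwise it is an explicit NO_CALL.

The assembled eVCF contains all variant records of the input gVCF plus one
record per catalog site not already present as a variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from evcfkit.errors import OverlapError
from evcfkit.genotypes import CallClass, CallSource, GenotypeCall, classify_gt_indices
from evcfkit.site_catalog import SiteAnnotation, SiteRecord
from evcfkit.vcf_io import EvcfHeaderMeta, EvcfRecord, GvcfRecord, RecordKind

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfidencePolicy:
    """Thresholds a non-variant block must meet to support a hom-ref call.

    ``min_gqx`` is a genotype-quality floor (Q20 by default); ``min_dp`` is
    the minimum read depth over the block (depth 5 matches the coverage rule
    used for gap detection); ``require_pass`` demands the PASS filter label.
    A block with a missing GQX or depth fails any finite threshold —
    conservative for clinical calls.
    """

    min_gqx: float = 20.0
    min_dp: int = 5
    require_pass: bool = True

    def __post_init__(self) -> None:
        if self.min_gqx < 0 or self.min_dp < 0:
            raise ValueError("policy thresholds must be non-negative")

    def block_passes(self, block: GvcfRecord) -> bool:
        if self.require_pass and not block.is_pass:
            return False
        if block.gqx is None or block.gqx < self.min_gqx:
            return False
        depth = block.min_dp if block.min_dp is not None else block.dp
        if depth is None or depth < self.min_dp:
            return False
        return True

    def render(self) -> str:
        return (
            f"min_gqx={self.min_gqx:g},min_dp={self.min_dp},"
            f"require_pass={str(self.require_pass).lower()}"
        )


@dataclass
class CallSummary:
    """Call-class accounting over one eVCF build.

    Invariant: ``n_sites`` equals the sum of the five class counts.
    ``conflicts`` lists catalog sites whose REF disagreed with the gVCF.
    """

    n_sites: int = 0
    n_hom_ref: int = 0
    n_het: int = 0
    n_hom_alt: int = 0
    n_het_alt: int = 0
    n_no_call: int = 0
    n_variant_records_passthrough: int = 0
    n_catalog_records_emitted: int = 0
    conflicts: list[SiteRecord] = field(default_factory=list)

    def count(self, call: GenotypeCall) -> None:
        self.n_sites += 1
        attr = {
            CallClass.HOM_REF: "n_hom_ref",
            CallClass.HET: "n_het",
            CallClass.HOM_ALT: "n_hom_alt",
            CallClass.HET_ALT: "n_het_alt",
            CallClass.NO_CALL: "n_no_call",
        }[call.call_class]
        setattr(self, attr, getattr(self, attr) + 1)
        if call.conflict:
            self.conflicts.append(call.site)

    @property
    def class_total(self) -> int:
        return (
            self.n_hom_ref
            + self.n_het
            + self.n_hom_alt
            + self.n_het_alt
            + self.n_no_call
        )

    def validate(self) -> None:
        if self.n_sites != self.class_total:
            raise AssertionError(
                f"call summary out of balance: {self.n_sites} sites vs "
                f"{self.class_total} class counts"
            )


class GvcfIndex:
    """Per-contig interval lookup over gVCF records.

    Point queries return every record whose [pos, end] span contains the
    position.  Two non-variant blocks may abut but never overlap
    (:class:`OverlapError`); a variant co-located inside a block is tolerated
    with a warning and takes precedence at resolution time.
    """

    def __init__(self, records: Iterable[GvcfRecord]):
        self._trees: dict[str, IntervalTree] = {}
        self._variants: dict[tuple[str, int], list[GvcfRecord]] = {}
        block_trees: dict[str, IntervalTree] = {}
        for rec in records:
            tree = self._trees.setdefault(rec.contig, IntervalTree())
            if rec.kind is RecordKind.BLOCK:
                btree = block_trees.setdefault(rec.contig, IntervalTree())
                hits = btree.overlap(rec.pos, rec.end + 1)
                if hits:
                    other = next(iter(hits)).data
                    raise OverlapError(
                        f"blocks overlap on {rec.contig}: "
                        f"[{other.pos},{other.end}] and [{rec.pos},{rec.end}]"
                    )
                btree.addi(rec.pos, rec.end + 1, rec)
            else:
                self._variants.setdefault((rec.contig, rec.pos), []).append(rec)
            tree.addi(rec.pos, rec.end + 1, rec)
        for contig, btree in block_trees.items():
            for iv in btree:
                block = iv.data
                for key, variants in self._variants.items():
                    if key[0] == contig and block.pos <= key[1] <= block.end:
                        logger.warning(
                            "variant at %s:%d lies inside block [%d,%d]; variant wins",
                            contig, key[1], block.pos, block.end,
                        )

    def query(self, contig: str, pos: int) -> list[GvcfRecord]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda r: (r.pos, r.end))

    def variant_at(self, contig: str, pos: int) -> Optional[GvcfRecord]:
        hits = self._variants.get((contig, pos))
        return hits[0] if hits else None

    def blocks_over(self, contig: str, start: int, end: int) -> list[GvcfRecord]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        out = [
            iv.data
            for iv in tree.overlap(start, end + 1)
            if iv.data.kind is RecordKind.BLOCK
        ]
        return sorted(out, key=lambda r: r.pos)


def index_gvcf(records: Iterable[GvcfRecord]) -> GvcfIndex:
    """Build the per-contig interval index used by :func:`resolve_genotype`."""
    return GvcfIndex(records)


def resolve_genotype(
    site: SiteRecord, index: GvcfIndex, policy: ConfidencePolicy = ConfidencePolicy()
) -> GenotypeCall:
    """Resolve the genotype at one catalog site.

    Never raises on missing evidence: every site resolves to a call or an
    explicit NO_CALL.  A variant record at the site's coordinate wins over
    block coverage; a REF disagreement between catalog and gVCF yields a
    NO_CALL flagged ``conflict``.
    """
    variant = index.variant_at(site.contig, site.pos)
    if variant is not None:
        if variant.ref != site.ref:
            return GenotypeCall(
                site=site,
                call_class=CallClass.NO_CALL,
                source=CallSource.NONE,
                conflict=True,
            )
        if variant.gt is None:
            return GenotypeCall(
                site=site, call_class=CallClass.NO_CALL, source=CallSource.NONE
            )
        allele_strings = (variant.ref,) + variant.alts
        try:
            alleles = (allele_strings[variant.gt[0]], allele_strings[variant.gt[1]])
        except IndexError:
            return GenotypeCall(
                site=site,
                call_class=CallClass.NO_CALL,
                source=CallSource.NONE,
                conflict=True,
            )
        return GenotypeCall(
            site=site,
            call_class=classify_gt_indices(variant.gt),
            alleles=alleles,
            source=CallSource.VARIANT_RECORD,
            gqx=variant.gqx,
            dp=variant.dp,
        )
    span_start, span_end = site.pos, site.end
    blocks = [
        b for b in index.blocks_over(site.contig, span_start, span_end)
        if policy.block_passes(b)
    ]
    covered_to = span_start - 1
    min_gqx: Optional[float] = None
    min_depth: Optional[float] = None
    for block in blocks:  # sorted, non-overlapping
        if block.pos > covered_to + 1:
            break
        covered_to = max(covered_to, block.end)
        if block.gqx is not None:
            min_gqx = block.gqx if min_gqx is None else min(min_gqx, block.gqx)
        depth = block.min_dp if block.min_dp is not None else block.dp
        if depth is not None:
            min_depth = depth if min_depth is None else min(min_depth, depth)
        if covered_to >= span_end:
            return GenotypeCall(
                site=site,
                call_class=CallClass.HOM_REF,
                alleles=(site.ref, site.ref),
                source=CallSource.BLOCK,
                gqx=min_gqx,
                dp=min_depth,
            )
    return GenotypeCall(site=site, call_class=CallClass.NO_CALL, source=CallSource.NONE)


def resolve_genotype_bruteforce(
    site: SiteRecord,
    records: Sequence[GvcfRecord],
    policy: ConfidencePolicy = ConfidencePolicy(),
) -> GenotypeCall:
    """Index-free oracle: linear scan plus per-base containment check.

    Deliberately naive — used to cross-check :func:`resolve_genotype`.
    """
    variant = None
    for rec in records:
        if (
            rec.kind is RecordKind.VARIANT
            and rec.contig == site.contig
            and rec.pos == site.pos
        ):
            variant = rec
            break
    if variant is not None:
        class _OneVariantIndex(GvcfIndex):
            def __init__(self) -> None:  # bypass tree construction
                self._trees = {}
                self._variants = {(variant.contig, variant.pos): [variant]}

        return resolve_genotype(site, _OneVariantIndex(), policy)
    min_gqx: Optional[float] = None
    min_depth: Optional[float] = None
    for pos in range(site.pos, site.end + 1):
        base_ok = False
        for rec in records:
            if (
                rec.kind is RecordKind.BLOCK
                and rec.contig == site.contig
                and rec.overlaps(pos)
                and policy.block_passes(rec)
            ):
                base_ok = True
                if rec.gqx is not None:
                    min_gqx = rec.gqx if min_gqx is None else min(min_gqx, rec.gqx)
                depth = rec.min_dp if rec.min_dp is not None else rec.dp
                if depth is not None:
                    min_depth = depth if min_depth is None else min(min_depth, depth)
                break
        if not base_ok:
            return GenotypeCall(
                site=site, call_class=CallClass.NO_CALL, source=CallSource.NONE
            )
    return GenotypeCall(
        site=site,
        call_class=CallClass.HOM_REF,
        alleles=(site.ref, site.ref),
        source=CallSource.BLOCK,
        gqx=min_gqx,
        dp=min_depth,
    )


def build_evcf(
    gvcf: Sequence[GvcfRecord],
    catalog: Sequence[SiteRecord],
    annotations: Optional[Mapping[tuple[str, int, str], SiteAnnotation]] = None,
    policy: ConfidencePolicy = ConfidencePolicy(),
    *,
    emit_nocalls: bool = True,
    meta: Optional[EvcfHeaderMeta] = None,
) -> tuple[list[EvcfRecord], CallSummary, EvcfHeaderMeta]:
    """Assemble the eVCF record set and the call-class summary.

    The output holds every VARIANT record of the input gVCF (annotated where
    it coincides with a catalog site) plus one explicit record per remaining
    catalog site: hom-ref records always, no-call records when
    ``emit_nocalls``.  Records are sorted by the gVCF's contig order, then
    position.  Annotations are looked up by (contig, pos, ref).
    """
    annotations = annotations or {}
    index = index_gvcf(gvcf)
    summary = CallSummary()
    contig_order = {c: i for i, c in enumerate(dict.fromkeys(r.contig for r in gvcf))}
    out: list[EvcfRecord] = []

    variant_annot: dict[tuple[str, int], dict] = {}
    for site in catalog:
        call = resolve_genotype(site, index, policy)
        summary.count(call)
        info = _annotation_info(annotations.get(site.key))
        if call.source is CallSource.VARIANT_RECORD:
            # genotype lives in the passthrough variant record; attach annotation
            variant_annot.setdefault((site.contig, site.pos), {}).update(info)
            continue
        if call.conflict:
            info["conflict"] = True
        if call.call_class is CallClass.NO_CALL and not emit_nocalls:
            continue
        gt = (0, 0) if call.call_class is CallClass.HOM_REF else None
        summary.n_catalog_records_emitted += 1
        out.append(
            EvcfRecord(
                contig=site.contig,
                pos=site.pos,
                ref=site.ref,
                alts=(),
                id=site.rsid,
                qual=None,
                filter=("PASS",) if call.call_class is CallClass.HOM_REF else (),
                info=info,
                gt=gt,
                gqx=call.gqx,
                dp=int(call.dp) if call.dp is not None else None,
            )
        )

    for rec in gvcf:
        if rec.kind is not RecordKind.VARIANT:
            continue
        summary.n_variant_records_passthrough += 1
        out.append(
            EvcfRecord(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alts=rec.alts,
                id=rec.id,
                qual=rec.qual,
                filter=rec.filter,
                info=dict(variant_annot.get((rec.contig, rec.pos), {})),
                gt=rec.gt,
                gqx=rec.gqx,
                dp=rec.dp,
            )
        )

    out.sort(key=lambda r: (contig_order.get(r.contig, len(contig_order)), r.contig, r.pos))
    summary.validate()
    if meta is None:
        meta = EvcfHeaderMeta(catalog_name="catalog", catalog_version="unversioned")
    meta.policy = policy.render()
    return out, summary, meta


def _annotation_info(annotation: Optional[SiteAnnotation]) -> dict:
    info: dict = {}
    if annotation is None:
        return info
    if annotation.known:
        info["known"] = True
    if annotation.gwascat_ids:
        info["gwascat_id"] = tuple(annotation.gwascat_ids)
        info["odds_ratio"] = tuple(annotation.odds_ratios)
    if annotation.clinical_significance:
        info["clnsig"] = tuple(sorted(annotation.clinical_significance))
    return info
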