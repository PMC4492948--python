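"""Callset comparison: array-allele normalization, probe-interference
filtering, and genotype concordance (sensitivity / specificity / concordance).

Definitions (truth-referenced, computed over mutually called sites):

* sensitivity — truth-variant sites also called variant by the test set /
  truth-variant sites;
* specificity — truth hom-ref sites called hom-ref by the test set / truth
  hom-ref sites;
* concordance — exact call-class-and-allele matches / mutually called sites.

Sites with a NO_CALL on either side are excluded from the three rates but
kept in the cross-tabulation margins and in the no-call rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from evcfkit.errors import EvcfKitError
from evcfkit.genotypes import CallClass, GenotypeCall, VARIANT_CLASSES
from evcfkit.site_catalog import SiteRecord
from evcfkit.vcf_io import ArrayGenotype

#: Fixed axis order of the cross-tabulation (truth rows, test columns).
CLASS_ORDER: tuple[CallClass, ...] = (
    CallClass.HOM_REF,
    CallClass.HET,
    CallClass.HOM_ALT,
    CallClass.HET_ALT,
    CallClass.NO_CALL,
)
_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ArrayAlignment:
    """Result of normalizing one array genotype against its expected site.

    ``call_class`` is ``None`` when the genotype is UNRESOLVABLE (alleles
    match neither directly nor via complement, or the site is
    strand-ambiguous).  ``method`` records whether the direct or the
    complemented orientation was used.
    """

    call_class: Optional[CallClass]
    alleles: Optional[tuple[str, str]] = None
    method: Optional[str] = None  # "direct" | "complement"
    reason: Optional[str] = None

    @property
    def resolved(self) -> bool:
        return self.call_class is not None


def _genotype_from_alleles(
    alleles: tuple[str, str], site: SiteRecord
) -> tuple[CallClass, tuple[str, str]]:
    ordered = tuple(sorted(alleles, key=lambda a: (a != site.ref, a)))
    n_ref = sum(1 for a in ordered if a == site.ref)
    if n_ref == 2:
        return CallClass.HOM_REF, ordered  # type: ignore[return-value]
    if n_ref == 1:
        return CallClass.HET, ordered  # type: ignore[return-value]
    if ordered[0] == ordered[1]:
        return CallClass.HOM_ALT, ordered  # type: ignore[return-value]
    return CallClass.HET_ALT, ordered  # type: ignore[return-value]


def align_array_alleles(
    ag: ArrayGenotype, site: SiteRecord, *, trust_strand: bool = False
) -> ArrayAlignment:
    """Normalize array alleles to the site's reference/alternate alleles.

    Alleles are matched directly against {REF} ∪ ALTs, then via base
    complement (arrays may report the opposite strand).  At strand-ambiguous
    sites (the allele set is its own complement, i.e. A/T or C/G) the two
    orientations cannot be told apart, so the genotype is UNRESOLVABLE
    unless ``trust_strand`` accepts the reported orientation.
    """
    if ag.is_no_call:
        return ArrayAlignment(call_class=CallClass.NO_CALL)
    alleles = (ag.allele_a, ag.allele_b)  # type: ignore[assignment]
    allowed = {site.ref, *site.alts}
    direct_ok = all(a in allowed for a in alleles)
    comp = tuple(_COMPLEMENT[a] for a in alleles)  # type: ignore[index]
    comp_ok = all(a in allowed for a in comp)
    ambiguous_site = {_COMPLEMENT.get(a) for a in allowed} == set(allowed)
    if direct_ok and comp_ok and ambiguous_site and not trust_strand:
        return ArrayAlignment(
            call_class=None, reason="strand-ambiguous site (A/T or C/G)"
        )
    if direct_ok:
        cls, ordered = _genotype_from_alleles(alleles, site)  # type: ignore[arg-type]
        return ArrayAlignment(call_class=cls, alleles=ordered, method="direct")
    if comp_ok:
        cls, ordered = _genotype_from_alleles(comp, site)  # type: ignore[arg-type]
        return ArrayAlignment(call_class=cls, alleles=ordered, method="complement")
    return ArrayAlignment(
        call_class=None,
        reason=f"alleles {alleles[0]}/{alleles[1]} match site alleles neither "
        "directly nor by complement",
    )


# ---------------------------------------------------------------------------
# probe interference


@dataclass
class ProbeFilterResult:
    """Targets kept/removed by the probe-interference filter.

    ``removal_reason`` maps a removed target's (contig, pos) to the nearest
    interfering variant span and its distance in bp.
    """

    kept: list[SiteRecord]
    removed: list[SiteRecord]
    removal_reason: dict[tuple[str, int], tuple[tuple[str, int, int], int]] = field(
        default_factory=dict
    )


Interfering = Union[SiteRecord, tuple[str, int], tuple[str, int, int]]


def _interfering_span(item: Interfering) -> tuple[str, int, int]:
    if isinstance(item, SiteRecord):
        return (item.contig, item.pos, item.end)
    if len(item) == 2:
        return (item[0], item[1], item[1])
    return item  # type: ignore[return-value]


def probe_interference_filter(
    targets: Sequence[SiteRecord],
    interfering: Iterable[Interfering],
    window_bp: int = 10,
) -> ProbeFilterResult:
    """Remove array targets with a polymorphism 1..``window_bp`` bp away.

    A variant directly at the probed base (distance 0) is the assayed site
    itself, not interference, and does not remove the target.  Indel
    distance is measured to the nearest base of the REF span.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    spans_by_contig: dict[str, list[tuple[int, int]]] = {}
    for item in interfering:
        contig, start, end = _interfering_span(item)
        spans_by_contig.setdefault(contig, []).append((start, end))
    for spans in spans_by_contig.values():
        spans.sort()
    result = ProbeFilterResult(kept=[], removed=[])
    for target in targets:
        nearest: Optional[tuple[tuple[str, int, int], int]] = None
        for start, end in spans_by_contig.get(target.contig, ()):
            if start > target.pos + window_bp:
                break
            if end < target.pos - window_bp:
                continue
            if target.pos < start:
                d = start - target.pos
            elif target.pos > end:
                d = target.pos - end
            else:
                d = 0
            if 1 <= d <= window_bp and (nearest is None or d < nearest[1]):
                nearest = ((target.contig, start, end), d)
        if nearest is None:
            result.kept.append(target)
        else:
            result.removed.append(target)
            result.removal_reason[(target.contig, target.pos)] = nearest
    return result


# ---------------------------------------------------------------------------
# callset comparison


@dataclass
class ConcordanceReport:
    """Genotype cross-tabulation and rates between two callsets.

    ``cross_tab`` is a 5×5 count matrix over :data:`CLASS_ORDER`
    (truth rows × test columns), covering every shared site including
    NO_CALL margins; ``n_compared`` is its total.  The three rates are
    computed over the mutually called subset (``n_mutually_called``).
    Rates are ``None`` when their denominator is empty.
    """

    cross_tab: np.ndarray
    n_compared: int
    n_mutually_called: int
    n_truth_only: int
    n_test_only: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    concordance: Optional[float]
    concordance_variant_sites: Optional[float]
    no_call_rate: float
    n_filtered_probes: int = 0

    def to_rows(self) -> list[dict]:
        """Cross-tab as tidy rows for TSV export."""
        rows = []
        for i, truth_cls in enumerate(CLASS_ORDER):
            for j, test_cls in enumerate(CLASS_ORDER):
                rows.append(
                    {
                        "truth": truth_cls.value,
                        "test": test_cls.value,
                        "count": int(self.cross_tab[i, j]),
                    }
                )
        return rows


CallLike = Union[GenotypeCall, CallClass]


def _normalize(call: CallLike) -> tuple[CallClass, Optional[tuple[str, str]]]:
    if isinstance(call, GenotypeCall):
        alleles = tuple(sorted(call.alleles)) if call.alleles else None
        return call.call_class, alleles  # type: ignore[return-value]
    return call, None


def compare_callsets(
    truth: Mapping[Hashable, CallLike],
    test: Mapping[Hashable, CallLike],
) -> ConcordanceReport:
    """Cross-tabulate two callsets keyed by site identity.

    Values may be :class:`GenotypeCall` (alleles compared when both sides
    carry them) or bare :class:`CallClass` (class-only comparison).  Raises
    :class:`EvcfKitError` when no shared site is called on both sides.
    """
    shared = [k for k in truth if k in test]
    cross = np.zeros((5, 5), dtype=np.int64)
    n_match = 0
    n_mutual = 0
    n_variant_mutual = 0
    n_variant_match = 0
    truth_variant = truth_variant_called = 0
    truth_homref = truth_homref_called = 0
    for key in shared:
        t_cls, t_alleles = _normalize(truth[key])
        s_cls, s_alleles = _normalize(test[key])
        cross[_CLASS_INDEX[t_cls], _CLASS_INDEX[s_cls]] += 1
        if t_cls is CallClass.NO_CALL or s_cls is CallClass.NO_CALL:
            continue
        n_mutual += 1
        match = t_cls is s_cls and (
            t_alleles is None or s_alleles is None or t_alleles == s_alleles
        )
        if match:
            n_match += 1
        if t_cls in VARIANT_CLASSES:
            truth_variant += 1
            if s_cls in VARIANT_CLASSES:
                truth_variant_called += 1
        if t_cls in VARIANT_CLASSES or s_cls in VARIANT_CLASSES:
            n_variant_mutual += 1
            if match:
                n_variant_match += 1
        if t_cls is CallClass.HOM_REF:
            truth_homref += 1
            if s_cls is CallClass.HOM_REF:
                truth_homref_called += 1
    if n_mutual == 0:
        raise EvcfKitError(
            "no site is present and called in both callsets; nothing to compare"
        )
    n_shared = len(shared)
    return ConcordanceReport(
        cross_tab=cross,
        n_compared=n_shared,
        n_mutually_called=n_mutual,
        n_truth_only=sum(1 for k in truth if k not in test),
        n_test_only=sum(1 for k in test if k not in truth),
        sensitivity=(truth_variant_called / truth_variant) if truth_variant else None,
        specificity=(truth_homref_called / truth_homref) if truth_homref else None,
        concordance=n_match / n_mutual,
        concordance_variant_sites=(
            n_variant_match / n_variant_mutual if n_variant_mutual else None
        ),
        no_call_rate=(n_shared - n_mutual) / n_shared,
    )
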