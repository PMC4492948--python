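"""Genotype call classes shared by the genotyping, catalog and concordance modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from evcfkit.site_catalog import SiteRecord


class CallClass(Enum):
    """Five-way diploid genotype classification.

    ``HET_ALT`` is the compound heterozygote (two different non-reference
    alleles); ``NO_CALL`` means the evidence failed the confidence policy so
    neither a variant nor a homozygous-reference genotype may be asserted.
    """

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HET_ALT = "het_alt"
    NO_CALL = "no_call"


#: Classes that assert presence of at least one non-reference allele.
VARIANT_CLASSES = frozenset({CallClass.HET, CallClass.HOM_ALT, CallClass.HET_ALT})


class CallSource(Enum):
    """Where the evidence for a genotype call came from."""

    VARIANT_RECORD = "variant_record"
    BLOCK = "block"
    NONE = "none"


@dataclass
class GenotypeCall:
    """A resolved genotype at one catalog site.

    ``alleles`` holds the two resolved allele strings for called genotypes and
    is ``None`` for a ``NO_CALL``.  ``gqx``/``dp`` carry the supporting quality
    (for block-derived hom-ref calls, the minimum over the covering blocks).
    ``conflict`` flags a reference-allele disagreement between the catalog and
    the gVCF at this position.
    """

    site: "SiteRecord"
    call_class: CallClass
    alleles: Optional[tuple[str, str]] = None
    source: CallSource = CallSource.NONE
    gqx: Optional[float] = None
    dp: Optional[float] = None
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.call_class is CallClass.NO_CALL and self.alleles is not None:
            raise ValueError("NO_CALL must not carry resolved alleles")

    @property
    def is_variant(self) -> bool:
        return self.call_class in VARIANT_CLASSES

    @property
    def is_called(self) -> bool:
        return self.call_class is not CallClass.NO_CALL


def classify_gt_indices(gt: tuple[int, int]) -> CallClass:
    """Map a pair of VCF allele indices to a call class."""
    a, b = sorted(gt)
    if a == 0 and b == 0:
        return CallClass.HOM_REF
    if a == 0:
        return CallClass.HET
    if a == b:
        return CallClass.HOM_ALT
    return CallClass.HET_ALT
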