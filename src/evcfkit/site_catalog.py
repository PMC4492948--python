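"""Clinical site catalogs: dbSNP-style sites, ClinVar significance, GWAS associations.

This module merges the catalogs that make a homozygous-reference genotype
clinically informative: positions where the reference genome itself carries the
minor, pathogenic, or GWAS risk allele.  It classifies reference alleles into
minor-allele-frequency bins and scores risk-allele zygosity for resolved
genotypes.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from evcfkit.errors import CatalogError
from evcfkit.genotypes import CallClass, GenotypeCall

_FREQ_SUM_TOL = 1e-6


@dataclass
class SiteRecord:
    """One catalog position: where to look and which alleles to expect.

    ``alt_freqs`` aligns with ``alts``; entries may be ``None`` when the
    catalog carries no frequency for that allele.  ``duplicate`` marks a
    record that repeated an earlier (contig, pos, ref, rsid) key on input.
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    rsid: Optional[str] = None
    alt_freqs: tuple[Optional[float], ...] = ()
    duplicate: bool = False

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        self.alt_freqs = tuple(self.alt_freqs)
        for alt in self.alts:
            if alt == self.ref:
                raise CatalogError(
                    f"site {self.contig}:{self.pos} has ALT equal to REF ({self.ref})"
                )
        for q in self.alt_freqs:
            if q is not None and not (0.0 <= q <= 1.0):
                raise CatalogError(
                    f"site {self.contig}:{self.pos} has allele frequency {q} outside [0, 1]"
                )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.ref)

    @property
    def end(self) -> int:
        """Last reference base of the site, 1-based inclusive."""
        return self.pos + len(self.ref) - 1


class MafBin(Enum):
    """Tightest minor-allele-frequency bin of the reference allele."""

    LT1 = "<1%"
    LT5 = "<5%"
    LT50 = "<50%"
    NOT_MINOR = "not_minor"


@dataclass
class ReferenceAlleleClass:
    """Is the reference base the minor allele at this site, and how rare is it?"""

    minor_on_ref: bool
    maf_bin: MafBin
    ref_allele_freq: Optional[float] = None


@dataclass
class GwasAssociation:
    """One GWAS-catalog trait association, remapped to coordinates by rsID."""

    rsid: str
    trait: str
    risk_allele: Optional[str] = None
    odds_ratio: Optional[float] = None
    contig: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise CatalogError(f"odds ratio must be positive, got {self.odds_ratio}")


@dataclass
class SiteAnnotation:
    """Merged clinical annotation attached to a site in the eVCF INFO field."""

    known: bool = False
    clinical_significance: frozenset[str] = frozenset()
    gwascat_ids: tuple[str, ...] = ()
    odds_ratios: tuple[Optional[float], ...] = ()
    risk_alleles: tuple[Optional[str], ...] = ()
    minor_on_ref: Optional[bool] = None
    maf_bin: Optional[MafBin] = None

    def __post_init__(self) -> None:
        if not (len(self.gwascat_ids) == len(self.odds_ratios) == len(self.risk_alleles)):
            raise CatalogError("gwascat_ids / odds_ratios / risk_alleles must align")

    @property
    def empty(self) -> bool:
        return not (self.known or self.clinical_significance or self.gwascat_ids)


@dataclass
class GwasZygosity:
    """Risk-allele dosage of a resolved genotype against one association."""

    risk_on_ref: bool
    risk_allele_dosage: int
    resolvable: bool


class CatalogIndex:
    """In-memory index of a site catalog by (contig, pos, ref) and by rsID.

    ``conflicts`` records positions where a lookup matched coordinates but
    disagreed on the reference allele (surfaced, never silently accepted).
    """

    def __init__(self, sites: Iterable[SiteRecord] = ()):
        self.by_key: dict[tuple[str, int, str], SiteRecord] = {}
        self.by_pos: dict[tuple[str, int], list[SiteRecord]] = defaultdict(list)
        self.by_rsid: dict[str, SiteRecord] = {}
        self.conflicts: list[tuple[SiteRecord, SiteRecord]] = []
        for site in sites:
            self.add(site)

    def add(self, site: SiteRecord) -> None:
        self.by_key.setdefault(site.key, site)
        self.by_pos[(site.contig, site.pos)].append(site)
        if site.rsid:
            self.by_rsid.setdefault(site.rsid, site)

    def __len__(self) -> int:
        return len(self.by_key)

    def contains(self, site: SiteRecord) -> bool:
        """Membership by (contig, pos, ref) with rsID fallback.

        A coordinate match with a different reference allele is recorded as a
        catalog conflict and does not count as membership.
        """
        if site.key in self.by_key:
            return True
        positional = self.by_pos.get((site.contig, site.pos), [])
        for other in positional:
            if other.ref != site.ref:
                self.conflicts.append((site, other))
        if site.rsid and site.rsid in self.by_rsid:
            return True
        return False


def load_gwas_catalog(
    source: Union[str, IO[str]],
    rsid_to_site: Mapping[str, SiteRecord],
    *,
    rsid_col: str = "rsid",
    trait_col: str = "trait",
    risk_allele_col: str = "risk_allele",
    odds_ratio_col: str = "odds_ratio",
) -> tuple[list[GwasAssociation], int]:
    """Read a GWAS-catalog TSV and remap coordinates through rsIDs.

    The catalog's own coordinates (a different genome build) are ignored:
    each association inherits contig/pos from the site catalog entry sharing
    its rsID.  Associations whose rsID is absent from ``rsid_to_site`` are
    dropped and counted, mirroring an rsID-keyed build remap.

    Returns ``(associations, n_dropped)``.
    """
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in (rsid_col, trait_col, risk_allele_col, odds_ratio_col):
        if col not in frame.columns:
            raise CatalogError(f"GWAS catalog is missing column {col!r}")
    associations: list[GwasAssociation] = []
    dropped = 0
    for row in frame.to_dict("records"):
        rsid = row[rsid_col].strip()
        site = rsid_to_site.get(rsid)
        if site is None:
            dropped += 1
            continue
        raw_or = row[odds_ratio_col].strip()
        try:
            odds_ratio: Optional[float] = float(raw_or)
        except ValueError:
            odds_ratio = None  # "NR" and friends: association kept, OR missing
        if odds_ratio is not None and not math.isfinite(odds_ratio):
            odds_ratio = None
        risk = row[risk_allele_col].strip().upper() or None
        if risk is not None and risk not in {"A", "C", "G", "T"}:
            risk = None
        associations.append(
            GwasAssociation(
                rsid=rsid,
                trait=row[trait_col].strip(),
                risk_allele=risk,
                odds_ratio=odds_ratio,
                contig=site.contig,
                pos=site.pos,
            )
        )
    return associations, dropped


def index_associations(
    associations: Iterable[GwasAssociation],
) -> dict[tuple[str, int], list[GwasAssociation]]:
    """Group remapped associations by (contig, pos) for annotation lookup."""
    by_pos: dict[tuple[str, int], list[GwasAssociation]] = defaultdict(list)
    for assoc in associations:
        if assoc.contig is not None and assoc.pos is not None:
            by_pos[(assoc.contig, assoc.pos)].append(assoc)
    return dict(by_pos)


def classify_reference_allele(site: SiteRecord) -> ReferenceAlleleClass:
    """Classify whether the reference genome carries the minor allele here.

    The reference allele frequency is 1 minus the sum of the known alternate
    allele frequencies.  ``minor_on_ref`` is strict (< 0.5); a tie at exactly
    0.5 is NOT_MINOR.  The bin is the tightest one containing the frequency.
    """
    known = [q for q in site.alt_freqs if q is not None]
    if not known:
        raise CatalogError(
            f"site {site.contig}:{site.pos} has no alternate allele frequency"
        )
    total_alt = sum(known)
    if total_alt > 1.0 + _FREQ_SUM_TOL:
        raise CatalogError(
            f"site {site.contig}:{site.pos} allele frequencies sum to {total_alt:.6f} > 1"
        )
    ref_freq = max(0.0, 1.0 - total_alt)
    if ref_freq >= 0.5:
        return ReferenceAlleleClass(False, MafBin.NOT_MINOR, ref_freq)
    if ref_freq < 0.01:
        bin_ = MafBin.LT1
    elif ref_freq < 0.05:
        bin_ = MafBin.LT5
    else:
        bin_ = MafBin.LT50
    return ReferenceAlleleClass(True, bin_, ref_freq)


def annotate_site(
    site: SiteRecord,
    dbsnp: Optional[CatalogIndex] = None,
    clinvar: Optional[Mapping[tuple[str, int, str], Iterable[str]]] = None,
    gwas: Optional[Mapping[tuple[str, int], Sequence[GwasAssociation]]] = None,
) -> SiteAnnotation:
    """Merge catalog evidence for one site into a single annotation.

    ``known`` means membership in the dbSNP-style catalog by (contig, pos,
    ref) or rsID.  All GWAS associations at the coordinate are attached as
    aligned lists.  Reference-allele classification is filled in when the
    site carries frequencies.  Absence of matches yields an empty annotation.
    """
    known = bool(dbsnp is not None and dbsnp.contains(site))
    significance: frozenset[str] = frozenset()
    if clinvar is not None:
        significance = frozenset(clinvar.get(site.key, ()))
    gwascat_ids: list[str] = []
    odds_ratios: list[Optional[float]] = []
    risk_alleles: list[Optional[str]] = []
    if gwas is not None:
        for assoc in gwas.get((site.contig, site.pos), ()):
            gwascat_ids.append(assoc.rsid)
            odds_ratios.append(assoc.odds_ratio)
            risk_alleles.append(assoc.risk_allele)
    minor_on_ref: Optional[bool] = None
    maf_bin: Optional[MafBin] = None
    if any(q is not None for q in site.alt_freqs):
        ref_class = classify_reference_allele(site)
        minor_on_ref = ref_class.minor_on_ref
        maf_bin = ref_class.maf_bin
    return SiteAnnotation(
        known=known,
        clinical_significance=significance,
        gwascat_ids=tuple(gwascat_ids),
        odds_ratios=tuple(odds_ratios),
        risk_alleles=tuple(risk_alleles),
        minor_on_ref=minor_on_ref,
        maf_bin=maf_bin,
    )


def classify_gwas_zygosity(
    call: GenotypeCall, site: SiteRecord, assoc: GwasAssociation
) -> GwasZygosity:
    """Count risk-allele copies in a resolved genotype.

    ``risk_on_ref`` says whether the reference genome itself carries the risk
    allele — the case where a homozygous-reference genotype means two risk
    copies.  ``resolvable`` is False when the risk allele is neither the
    reference nor any alternate allele, so the assay cannot observe it.
    """
    if call.call_class is CallClass.NO_CALL:
        raise ValueError("cannot score risk-allele zygosity of a NO_CALL")
    if assoc.risk_allele is None:
        raise ValueError("association has no annotated risk allele")
    risk = assoc.risk_allele
    risk_on_ref = risk == site.ref
    resolvable = risk == site.ref or risk in site.alts
    if call.alleles is not None:
        alleles: tuple[str, ...] = call.alleles
    elif call.call_class is CallClass.HOM_REF:
        alleles = (site.ref, site.ref)
    else:  # pragma: no cover - called genotypes always carry alleles
        raise ValueError("called genotype is missing resolved alleles")
    dosage = sum(1 for a in alleles if a == risk) if resolvable else 0
    return GwasZygosity(
        risk_on_ref=risk_on_ref, risk_allele_dosage=dosage, resolvable=resolvable
    )
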