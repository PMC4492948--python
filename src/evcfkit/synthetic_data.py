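"""Deterministic synthetic genomes, catalogs, gVCFs and array reports.

Everything downstream is testable against known truth: a random reference
sequence (optionally with embedded GC-rich windows and AT-dinucleotide
runs), a catalog of biallelic SNV sites with population alternate-allele
frequencies, Hardy–Weinberg genotypes, a gVCF that encodes them
(variant records for het/hom-alt sites, confidence-passing non-variant
blocks elsewhere, confidence-failing blocks over a configurable no-call
mask), and a genotyping-array report with injected genotype errors and
strand flips.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from evcfkit.errors import EvcfKitError
from evcfkit.genotypes import CallClass
from evcfkit.site_catalog import SiteRecord
from evcfkit.vcf_io import ArrayGenotype, GvcfRecord, RecordKind

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# GQX ranges bracketing the default confidence floor of 20
_PASS_GQX = (30, 100)   # high-confidence blocks: uniform [30, 99]
_FAIL_GQX = (0, 20)     # low-confidence blocks: uniform [0, 19]
_PASS_MIN_DP = (20, 41)
_VARIANT_DP = (20, 61)
_MAX_BLOCK_LEN = 300


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``alt_freq_range`` bounds the uniform draw of each site's alternate
    allele frequency; ``nocall_fraction`` is the share of the genome placed
    under low-confidence blocks; ``array_error_rate`` perturbs array
    genotypes to a different class; ``strand_flip_rate`` reports array
    alleles on the opposite strand.
    """

    genome_length: int = 100_000
    n_sites: int = 1_000
    alt_freq_range: tuple[float, float] = (0.005, 0.995)
    nocall_fraction: float = 0.0
    array_error_rate: float = 0.0
    strand_flip_rate: float = 0.0
    gc_content: float = 0.41
    contig: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nocall_fraction", "array_error_rate", "strand_flip_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise EvcfKitError(f"{name} must be in [0, 1], got {value}")
        if self.n_sites > self.genome_length:
            raise EvcfKitError("n_sites cannot exceed genome_length")


@dataclass
class FeatureSpec:
    """A sequence feature to embed: a GC-content window or an AT-dinucleotide run."""

    kind: str  # "gc_window" | "at_run"
    length: int
    gc: Optional[float] = None  # target GC fraction for gc_window
    start: Optional[int] = None  # 1-based; chosen automatically when None


@dataclass
class PlacedFeature:
    kind: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class TruthSet:
    """Ground truth behind one synthetic dataset."""

    reference: str
    contig: str
    sites: list[SiteRecord]
    genotypes: dict[tuple[str, int, str], CallClass]
    nocall_mask: list[tuple[int, int]] = field(default_factory=list)

    def variant_positions(self) -> set[int]:
        return {
            site.pos
            for site in self.sites
            if self.genotypes[site.key] in (CallClass.HET, CallClass.HOM_ALT)
        }


@dataclass
class SimulatedArrayCall:
    """Per-site log of what the array-report generator actually did."""

    reported_class: CallClass
    alleles: tuple[str, str]
    erroneous: bool
    flipped: bool


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: TruthSet
    gvcf: list[GvcfRecord]
    array_report: list[ArrayGenotype]
    array_log: dict[tuple[str, int, str], SimulatedArrayCall]


def generate_reference(
    length: int,
    gc_content: float = 0.41,
    features: Sequence[FeatureSpec] = (),
    seed: int = 0,
    *,
    gc_window: int = 100,
) -> tuple[str, list[PlacedFeature]]:
    """Draw a random DNA sequence with optional embedded features.

    GC-window features are aligned to ``gc_window`` tile boundaries so the
    window classifier sees them whole, and are built with an exact G+C base
    count (ceil of gc × length).  AT runs are exact ATAT… repeats flanked by
    G/C so they do not extend.  Features without an explicit start are laid
    out left to right, one per tile, separated by at least one tile.
    """
    if length < 1:
        raise EvcfKitError("reference length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    seq = rng.choice(_BASES, size=length, p=p)
    placed: list[PlacedFeature] = []
    cursor = 0  # 0-based offset of the next automatic slot
    for spec in features:
        if spec.length > length:
            raise EvcfKitError(
                f"feature of length {spec.length} cannot fit a {length} bp genome"
            )
        if spec.start is not None:
            start0 = spec.start - 1
        else:
            start0 = ((cursor + gc_window - 1) // gc_window) * gc_window
            cursor = start0 + spec.length + gc_window
        if start0 + spec.length > length:
            raise EvcfKitError("features do not fit into the genome")
        if spec.kind == "gc_window":
            if spec.gc is None:
                raise EvcfKitError("gc_window feature requires a gc fraction")
            n_gc = int(np.ceil(spec.gc * spec.length))
            bases = np.array(["G", "C"])[rng.integers(0, 2, size=spec.length)]
            at_idx = rng.permutation(spec.length)[: spec.length - n_gc]
            bases[at_idx] = np.array(["A", "T"])[rng.integers(0, 2, size=len(at_idx))]
            seq[start0 : start0 + spec.length] = bases
        elif spec.kind == "at_run":
            run = np.array(["A", "T"] * ((spec.length + 1) // 2))[: spec.length]
            seq[start0 : start0 + spec.length] = run
            if start0 > 0:
                seq[start0 - 1] = "G"
            if start0 + spec.length < length:
                seq[start0 + spec.length] = "C"
        else:
            raise EvcfKitError(f"unknown feature kind {spec.kind!r}")
        placed.append(PlacedFeature(spec.kind, start0 + 1, start0 + spec.length))
    return "".join(seq), placed


def simulate_sites(
    reference: str,
    n_sites: int,
    alt_freq_range: tuple[float, float] = (0.005, 0.995),
    seed: int = 0,
    contig: str = "chr1",
) -> list[SiteRecord]:
    """Place biallelic SNV catalog sites at distinct random positions.

    Each site's alternate allele frequency is drawn uniformly from
    ``alt_freq_range``; the alternate base is a random non-reference base.
    Sites are returned sorted by position with sequential rsIDs.
    """
    if n_sites > len(reference):
        raise EvcfKitError("more sites requested than reference positions")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.permutation(len(reference))[:n_sites]) + 1
    low, high = alt_freq_range
    freqs = rng.uniform(low, high, size=n_sites)
    sites: list[SiteRecord] = []
    for i, (pos, q) in enumerate(zip(positions.tolist(), freqs.tolist())):
        ref = reference[pos - 1].upper()
        if ref == "N":
            ref = "A"
        others = [b for b in "ACGT" if b != ref]
        alt = others[int(rng.integers(0, 3))]
        sites.append(
            SiteRecord(
                contig=contig,
                pos=pos,
                ref=ref,
                alts=(alt,),
                rsid=f"rs{100000 + i}",
                alt_freqs=(float(q),),
            )
        )
    return sites


def simulate_genotypes(
    sites: Sequence[SiteRecord], seed: int = 0
) -> dict[tuple[str, int, str], CallClass]:
    """Draw Hardy–Weinberg genotypes from each site's alternate frequency q:
    P(hom-ref) = (1−q)², P(het) = 2q(1−q), P(hom-alt) = q².
    """
    rng = np.random.default_rng(seed)
    genotypes: dict[tuple[str, int, str], CallClass] = {}
    for site in sites:
        if not site.alt_freqs or site.alt_freqs[0] is None:
            raise EvcfKitError(f"site {site.contig}:{site.pos} has no alt frequency")
        q = site.alt_freqs[0]
        if not (0.0 < q < 1.0):
            raise EvcfKitError(f"alt frequency must be in (0, 1), got {q}")
        u = rng.random()
        if u < (1 - q) ** 2:
            genotypes[site.key] = CallClass.HOM_REF
        elif u < (1 - q) ** 2 + 2 * q * (1 - q):
            genotypes[site.key] = CallClass.HET
        else:
            genotypes[site.key] = CallClass.HOM_ALT
    return genotypes


def _place_nocall_mask(
    length: int,
    fraction: float,
    variant_positions: set[int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Uniformly place non-overlapping low-confidence intervals.

    Intervals avoid variant positions (a variant record supersedes the block
    anyway); at fraction 1 the whole non-variant genome is masked.
    """
    if fraction <= 0:
        return []
    if fraction >= 1.0:
        mask = np.ones(length, dtype=bool)
        for pos in variant_positions:
            mask[pos - 1] = False
        return _mask_to_intervals(mask)
    target = int(round(fraction * length))
    mask = np.zeros(length, dtype=bool)
    covered = 0
    tries = 0
    max_tries = 200 * max(1, target // 20)
    while covered < target and tries < max_tries:
        tries += 1
        ivl_len = int(rng.integers(20, 201))
        start0 = int(rng.integers(0, length))
        end0 = min(length, start0 + ivl_len)
        if mask[start0:end0].any():
            continue
        if variant_positions.intersection(range(start0 + 1, end0 + 1)):
            continue
        mask[start0:end0] = True
        covered += end0 - start0
    return _mask_to_intervals(mask)


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1  # to 1-based
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def make_truth(config: SimulationConfig) -> TruthSet:
    """Generate reference, catalog sites, genotypes and the no-call mask."""
    rng = np.random.default_rng(config.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    reference, _ = generate_reference(
        config.genome_length, config.gc_content, seed=sub[0]
    )
    sites = simulate_sites(
        reference, config.n_sites, config.alt_freq_range, seed=sub[1],
        contig=config.contig,
    )
    genotypes = simulate_genotypes(sites, seed=sub[2])
    truth = TruthSet(
        reference=reference, contig=config.contig, sites=sites, genotypes=genotypes
    )
    truth.nocall_mask = _place_nocall_mask(
        config.genome_length,
        config.nocall_fraction,
        truth.variant_positions(),
        np.random.default_rng(sub[3]),
    )
    return truth


def emit_gvcf(truth: TruthSet, config: SimulationConfig) -> list[GvcfRecord]:
    """Encode the truth set as a gVCF record sequence.

    Het/hom-alt sites become PASS variant records; every other position is
    covered by non-variant blocks — confidence-passing ones (GQX 30–99,
    MIN_DP 20–40) outside the no-call mask, failing ones (GQX 0–19) inside
    it.  Blocks are capped at 300 bp to mimic realistic block granularity.
    """
    rng = np.random.default_rng([config.seed, 17])
    length = config.genome_length
    # per-base state: 0 = passing block, 1 = failing block, 2 = variant
    state = np.zeros(length, dtype=np.uint8)
    for start, end in truth.nocall_mask:
        state[start - 1 : end] = 1
    variant_sites = [
        site
        for site in truth.sites
        if truth.genotypes[site.key] in (CallClass.HET, CallClass.HOM_ALT)
    ]
    for site in variant_sites:
        state[site.pos - 1] = 2
    records: list[GvcfRecord] = []
    variants_by_pos = {site.pos: site for site in variant_sites}
    change = np.flatnonzero(np.diff(state)) + 1
    boundaries = [0, *change.tolist(), length]
    for left, right in zip(boundaries[:-1], boundaries[1:]):
        kind = state[left]
        if kind == 2:
            for pos0 in range(left, right):
                site = variants_by_pos[pos0 + 1]
                cls = truth.genotypes[site.key]
                gt = (0, 1) if cls is CallClass.HET else (1, 1)
                gqx = float(rng.integers(*_PASS_GQX))
                records.append(
                    GvcfRecord(
                        contig=truth.contig,
                        pos=site.pos,
                        ref=site.ref,
                        kind=RecordKind.VARIANT,
                        id=site.rsid,
                        alts=site.alts,
                        qual=gqx,
                        filter=("PASS",),
                        gt=gt,
                        gqx=gqx,
                        dp=int(rng.integers(*_VARIANT_DP)),
                    )
                )
            continue
        pos0 = left
        while pos0 < right:
            block_end0 = min(right, pos0 + int(rng.integers(50, _MAX_BLOCK_LEN + 1)))
            if kind == 0:
                gqx = float(rng.integers(*_PASS_GQX))
                min_dp = int(rng.integers(*_PASS_MIN_DP))
            else:
                gqx = float(rng.integers(*_FAIL_GQX))
                min_dp = int(rng.integers(*_PASS_MIN_DP))
            records.append(
                GvcfRecord(
                    contig=truth.contig,
                    pos=pos0 + 1,
                    ref=truth.reference[pos0],
                    kind=RecordKind.BLOCK,
                    filter=("PASS",),
                    end=block_end0,
                    gt=(0, 0),
                    gqx=gqx,
                    dp=min_dp + int(rng.integers(0, 10)),
                    min_dp=min_dp,
                )
            )
            pos0 = block_end0
    return records


_CLASS_TO_ALLELES = {
    CallClass.HOM_REF: lambda s: (s.ref, s.ref),
    CallClass.HET: lambda s: (s.ref, s.alts[0]),
    CallClass.HOM_ALT: lambda s: (s.alts[0], s.alts[0]),
}


def emit_array_report(
    truth: TruthSet, config: SimulationConfig
) -> tuple[list[ArrayGenotype], dict[tuple[str, int, str], SimulatedArrayCall]]:
    """Render the truth genotypes as an array report with injected noise.

    With probability ``array_error_rate`` a site's genotype is perturbed to
    one of the two other classes (uniformly); independently, with
    probability ``strand_flip_rate`` the alleles are complemented.  The
    returned log records exactly what happened at each site.
    """
    rng = np.random.default_rng([config.seed, 23])
    rows: list[ArrayGenotype] = []
    log: dict[tuple[str, int, str], SimulatedArrayCall] = {}
    classes = (CallClass.HOM_REF, CallClass.HET, CallClass.HOM_ALT)
    for site in truth.sites:
        true_cls = truth.genotypes[site.key]
        reported = true_cls
        erroneous = rng.random() < config.array_error_rate
        if erroneous:
            others = [c for c in classes if c is not true_cls]
            reported = others[int(rng.integers(0, len(others)))]
        alleles = _CLASS_TO_ALLELES[reported](site)
        flipped = rng.random() < config.strand_flip_rate
        if flipped:
            alleles = (_COMPLEMENT[alleles[0]], _COMPLEMENT[alleles[1]])
        rows.append(
            ArrayGenotype(
                marker_id=site.rsid or f"{site.contig}:{site.pos}",
                contig=site.contig,
                pos=site.pos,
                allele_a=alleles[0],
                allele_b=alleles[1],
            )
        )
        log[site.key] = SimulatedArrayCall(
            reported_class=reported, alleles=alleles, erroneous=erroneous,
            flipped=flipped,
        )
    return rows, log


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """One-call pipeline: truth, gVCF and array report for a config."""
    truth = make_truth(config)
    gvcf = emit_gvcf(truth, config)
    array_report, array_log = emit_array_report(truth, config)
    return SimulatedDataset(
        config=config,
        truth=truth,
        gvcf=gvcf,
        array_report=array_report,
        array_log=array_log,
    )
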