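# Methods

## Genotype resolution from gVCF blocks

The central operation resolves a five-way genotype
(hom-ref / het / hom-alt / het-alt / no-call) at each site of a clinical
catalog from a single-sample gVCF.

A gVCF record is either a **variant record** (ALT present, genotype in
`GT`) or a **non-variant block** (ALT `.`), whose span runs from `POS` to
the `END` key, 1-based inclusive, with block-level summaries `GQX`
(genotype-quality floor over the block) and `MIN_DP` (minimum read depth).
Both the INFO and FORMAT conventions for `END`/`GQX`/`MIN_DP` occur in the
wild; the parser accepts either, preferring FORMAT when both are present.

Resolution rules, in order:

1. A variant record at the site's exact coordinate supplies the genotype
   from its allele indices. The confidence policy is *not* re-applied —
   variant records carry their caller's FILTER status, which is copied
   through. A disagreement between the catalog's REF and the record's REF
   resolves to no-call with a `conflict` flag (one bad catalog line must not
   abort a clinical run).
2. Otherwise the site's full REF span (`POS … POS + len(REF) − 1`) must be
   covered by non-variant blocks that pass the policy. Hom-ref is asserted
   with the minimum GQX/MIN_DP over the covering blocks as its supporting
   quality. Partial coverage — including an indel REF span that runs one
   base past a block — is not hom-ref.
3. Anything else is an explicit no-call.

### Confidence policy

| parameter | default | meaning |
|---|---|---|
| `min_gqx` | 20 | Q20 genotype-quality floor a block must meet |
| `min_dp` | 5 | depth floor, matching the coverage rule used for gap detection |
| `require_pass` | true | block FILTER must contain `PASS` |

There is no community-standard numeric definition of a "high-confidence"
block, so these defaults encode the conventional Q20 floor and the same
depth-5 rule the coverage analyses use; all three are configurable per run
and recorded in the eVCF header (`##evcfPolicy=`). A block with missing GQX
or depth fails any finite threshold — deliberately conservative: an
unquantified block never supports a clinical hom-ref assertion. A block
with FILTER `.` (unfiltered) likewise does not count as PASS.

### eVCF layout

The output is ordinary VCF 4.2. Variant records pass through unchanged
(annotated in INFO where they coincide with a catalog site). Each remaining
catalog site gets one record: hom-ref as `ALT .` with `GT 0/0`, no-call as
`GT ./.`. No-call records are emitted by default — suppressing them would
re-create exactly the hom-ref/no-call ambiguity the format exists to
remove — and can be disabled (`--skip-nocalls`). Catalog provenance is a
single `##siteCatalog=<name=…,version=…>` header line; name and version are
mandatory whenever catalog records are present. Declared INFO keys:
`known` (catalog membership flag), `gwascat_id`/`odds_ratio` (aligned
comma-joined lists, one entry per GWAS association at the coordinate),
`clnsig` (clinical-significance labels), `conflict` (flag).

The gVCF/eVCF reader and writer are implemented at line level in
`vcf_io` rather than through a general VCF library: the block extension and
the explicit hom-ref/no-call record layout are the point of the package,
and round-trip identity over that dialect requires full control of
serialization. A test uses pysam as an independent VCF implementation to
confirm that emitted eVCFs parse as valid VCF.

## Catalogs and reference-allele audit

Sites-only VCFs carry the catalog: allele frequencies are read from a
configurable INFO key in the dbSNP `CAF` layout (reference frequency first,
then one per ALT), clinical significance from a configurable key
(`CLNSIG` by default, an open label set). GWAS-catalog TSVs are joined to
coordinates purely through rsIDs — an rsID-keyed remap between genome
builds — and associations whose rsID is absent from the site catalog are
dropped and counted rather than guessed at. Unparsable odds-ratio fields
("NR") keep the association with the odds ratio missing.

The reference allele's frequency is `1 − Σ` alternate frequencies. The
reference carries the **minor allele** when that frequency is strictly
below 0.5 (a tie is not minor); the reported bin is the tightest of
MAF < 1%, < 5%, < 50%. Risk-allele zygosity counts risk-allele copies in a
resolved genotype and flags the clinically loaded case where the risk
allele *is* the reference allele, so a hom-ref genotype means two risk
copies; a risk allele that is neither REF nor any ALT is reported
unresolvable instead of silently counted as zero.

## Concordance

Definitions, computed over sites called on both sides (a no-call on either
side excludes the site from the rates but stays in the 5×5 cross-tab and
the no-call rate):

* **sensitivity** = truth-variant sites also called variant by the test
  callset / truth-variant sites;
* **specificity** = truth hom-ref sites called hom-ref / truth hom-ref
  sites;
* **concordance** = exact class-and-allele matches / mutually called sites
  (a variant-sites-only concordance is also emitted, since either
  denominator convention is defensible).

Array genotypes are normalized against the expected site alleles directly,
then via base complement (arrays may report the opposite strand). At
strand-ambiguous sites (A/T or C/G — the allele set is its own complement)
the two orientations are indistinguishable, so such sites default to
unresolvable and are excluded from the rates; `--trust-strand` accepts the
reported orientation. The probe-interference filter removes a target when
any polymorphism lies 1–10 bp (configurable window) from the probed base,
with indel distance measured to the nearest base of the REF span; distance
0 is the assayed site itself, not interference.

## Coverage QC

A base is **covered** when read depth ≥ 5, mapping quality ≥ 10 and
basecall quality ≥ 10 (all three thresholds configurable; ≥ is the default
comparison, strict > selectable). A **gap** is a maximal run of more than
10 non-covered bases. Because "covered" conjoins three criteria, its
complement (any criterion failing) is the default gap-base definition; the
stricter alternative — all three failing simultaneously — is available as
`gap_logic="all"`.

GC windows are non-overlapping 100 bp tiles from the contig start (stride
configurable); classes are high ≥ 75% and extreme ≥ 85% G+C, with N bases
excluded from numerator and denominator. AT-dinucleotide runs are maximal
alternating A/T stretches (no AA/TT) of ≥ 30 bp. Coverage sub-sampling is
modeled as per-base binomial thinning — each depth `d` becomes
Binomial(d, target/current mean) — which preserves mean-coverage semantics
without read-level data; per-base quality summaries (means vs minima over
reads) are consumed as whatever the upstream tool emitted, as a
pass-through.

## Synthetic data: what it emulates, what it does not

The generator produces the full input set with known truth: a random
reference (41% GC, the human genome-wide value; exact-count GC windows and
flanked AT runs embeddable for the context classifiers), a catalog of
biallelic SNVs at distinct positions with alternate-allele frequencies
drawn uniformly from (0.005, 0.995) — wide enough to cover rare,
low-frequency and common reference-minor sites — Hardy–Weinberg genotypes
(P(hom-ref) = (1−q)², P(het) = 2q(1−q), P(hom-alt) = q²), a gVCF encoding
them, and an array report.

gVCF emission covers every non-variant base with blocks of 50–300 bp.
Passing blocks draw GQX uniformly from [30, 99] and MIN_DP from [20, 40];
blocks inside the no-call mask draw GQX from [0, 19] — the two ranges
bracket the default GQX floor of 20 so the mask, and only the mask, fails
the default policy. Mask intervals (20–200 bp) are placed uniformly at
random without overlapping each other or variant positions; their total
length approximates `nocall_fraction` × genome length. Array noise is
injected per site: with `array_error_rate` the genotype moves to one of the
other two classes, and independently with `strand_flip_rate` the alleles
are complemented; a log records exactly what happened at each site.

Deliberately not modeled: reads and sequencing error (genotypes are
asserted, not re-called), multi-allelic sites (hand-written fixtures cover
those), linkage, sex-chromosome hemizygosity, and indel catalog sites in
the simulator. Passing tests therefore demonstrate the correctness of the
resolution, accounting and comparison machinery under clean generative
assumptions — not robustness to caller artifacts in real gVCFs.

## Numerical and design notes

* Coordinates are 1-based inclusive everywhere internally (VCF `POS`/`END`
  semantics); BED input is converted on read.
* Two non-variant blocks may abut but never overlap (an error); a variant
  record co-located inside a block is tolerated with a warning, and the
  variant wins at resolution time.
* Frequency sums may exceed 1 by at most 1e-6 before the catalog is
  rejected as inconsistent; the reference frequency is clamped at 0.
* Multiple GWAS associations at one coordinate are kept as aligned lists
  (INFO `Number=.`).
* Block-derived hom-ref calls report the *minimum* GQX/MIN_DP over covering
  blocks — the weakest link, not an average.
* Interval lookup uses an interval tree; an index-free brute-force resolver
  (linear scan, per-base containment) is kept in the package as the oracle
  the tests compare against.
* Simulation problem sizes used by the test suite and the acceptance script
  (20–200 kb genomes, 150–5,000 catalog sites, up to 100 replicates for the
  no-call-rate check) were chosen to give stable binomial statistics at
  desk scale.

## Known limitations

* Single-sample only, matching the gVCF model; no multi-sample eVCF.
* No structural-variant or symbolic ALT alleles, no BAM/CRAM input.
* The hg38↔hg19-style rsID join trusts rsIDs; merged or multi-mapped rsIDs
  surface as dropped/flagged, never remapped heuristically.
* The observed no-call rate among hom-ref catalog sites runs a fraction of
  a percent above the nominal mask fraction because mask intervals avoid
  variant positions, slightly concentrating them in the space where
  hom-ref sites live; the bias is far inside the binomial noise at the
  tested scales.
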