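"""Streaming readers and writers for gVCF, sites-only VCF, eVCF and array reports.

The gVCF dialect handled here is the block-extension of VCF 4.x: non-variant
stretches are stored as single records carrying an END coordinate and
block-level quality summaries (GQX, MIN_DP), so every genomic position has a
confidence-qualified call.  The eVCF writer produces a standard VCF that adds
one explicit record per catalog site not already present as a variant —
homozygous-reference records with ALT ``.`` and GT ``0/0``, and (optionally)
no-call records with GT ``./.`` — with catalog provenance in the header.

All coordinates are 1-based inclusive, matching VCF POS/END semantics.
MIN_DP and GQX are accepted from either INFO or FORMAT (both conventions
exist in the wild); FORMAT wins when both are present.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence, Union

import pandas as pd

from evcfkit.errors import (
    ArrayReportError,
    InvalidRecordError,
    RecordOrderError,
    SerializationError,
    VcfParseError,
)
from evcfkit.site_catalog import SiteRecord

Source = Union[str, Path, IO[str], Iterable[str]]

_VALID_BASES = frozenset("ACGT")


class RecordKind(Enum):
    VARIANT = "variant"
    BLOCK = "block"


@dataclass
class GvcfRecord:
    """One gVCF line: a variant call or a non-variant block.

    For a BLOCK, ``end`` comes from the END key and ``min_dp`` summarizes the
    lowest read depth across the block; ``alts`` is empty and ``gt`` is the
    homozygous-reference genotype (0, 0) or missing.  For a VARIANT, ``end``
    is ``pos + len(ref) - 1``.
    """

    contig: str
    pos: int
    ref: str
    kind: RecordKind
    id: Optional[str] = None
    alts: tuple[str, ...] = ()
    qual: Optional[float] = None
    filter: tuple[str, ...] = ()
    end: Optional[int] = None
    gt: Optional[tuple[int, int]] = None
    gqx: Optional[float] = None
    dp: Optional[int] = None
    min_dp: Optional[int] = None

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        self.filter = tuple(self.filter)
        if self.end is None:
            self.end = self.pos + len(self.ref) - 1
        if self.end < self.pos:
            raise InvalidRecordError(
                f"{self.contig}:{self.pos} has END={self.end} < POS"
            )
        if self.kind is RecordKind.BLOCK:
            if self.alts:
                raise InvalidRecordError("BLOCK record must not carry ALT alleles")
            if self.gt is not None and self.gt != (0, 0):
                raise InvalidRecordError(
                    f"BLOCK record at {self.contig}:{self.pos} has non-reference GT {self.gt}"
                )
        else:
            if not self.alts:
                raise InvalidRecordError("VARIANT record requires at least one ALT")

    @property
    def is_pass(self) -> bool:
        return "PASS" in self.filter

    def overlaps(self, pos: int) -> bool:
        return self.pos <= pos <= self.end  # type: ignore[operator]


@dataclass
class InfoKey:
    """An INFO field declaration for the eVCF header."""

    id: str
    number: str
    type: str
    description: str

    def header_line(self) -> str:
        return (
            f"##INFO=<ID={self.id},Number={self.number},Type={self.type},"
            f'Description="{self.description}">'
        )


#: INFO keys the eVCF builder emits; declared in every eVCF header.
DEFAULT_INFO_KEYS: tuple[InfoKey, ...] = (
    InfoKey("known", "0", "Flag", "Site present in the site catalog (e.g. dbSNP)"),
    InfoKey("gwascat_id", ".", "String", "GWAS catalog rsIDs associated with this site"),
    InfoKey("odds_ratio", ".", "Float", "Odds ratios aligned with gwascat_id"),
    InfoKey("clnsig", ".", "String", "Clinical significance labels for this site"),
    InfoKey("conflict", "0", "Flag", "Catalog REF allele disagrees with the gVCF"),
    InfoKey("END", "1", "Integer", "End position of a non-variant block"),
)


@dataclass
class EvcfHeaderMeta:
    """Provenance carried in the eVCF header.

    The catalog name and version identify the site list used to generate the
    file; they are mandatory whenever catalog-derived records are emitted.
    """

    catalog_name: str = ""
    catalog_version: str = ""
    source_gvcf: str = ""
    policy: str = ""
    extra_info_keys: tuple[InfoKey, ...] = DEFAULT_INFO_KEYS
    sample: str = "SAMPLE"


@dataclass
class EvcfRecord:
    """One eVCF line: a variant passthrough or an explicit catalog-site record.

    Catalog hom-ref records have empty ``alts`` (serialized ALT ``.``) and
    ``gt == (0, 0)``; no-call records have ``gt is None`` (serialized
    ``./.``).  ``info`` holds only keys declared in the header: flags map to
    ``True``, list-valued keys to tuples.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...] = ()
    id: Optional[str] = None
    qual: Optional[float] = None
    filter: tuple[str, ...] = ()
    info: dict = field(default_factory=dict)
    gt: Optional[tuple[int, int]] = None
    gqx: Optional[float] = None
    dp: Optional[int] = None

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        self.filter = tuple(self.filter)

    @property
    def is_catalog_site(self) -> bool:
        """True for records added for a catalog site (not plain variant passthrough)."""
        return not self.alts or "known" in self.info or "conflict" in self.info


@dataclass
class ArrayGenotype:
    """One genotyping-array call: two alleles, or both missing for an array no-call."""

    marker_id: str
    contig: str
    pos: int
    allele_a: Optional[str]
    allele_b: Optional[str]
    matched: bool = True

    def __post_init__(self) -> None:
        missing = (self.allele_a is None, self.allele_b is None)
        if any(missing) and not all(missing):
            raise ArrayReportError(
                f"marker {self.marker_id}: half-missing genotype {self.allele_a}/{self.allele_b}"
            )
        for a in (self.allele_a, self.allele_b):
            if a is not None and a not in _VALID_BASES:
                raise ArrayReportError(f"marker {self.marker_id}: invalid allele {a!r}")

    @property
    def is_no_call(self) -> bool:
        return self.allele_a is None


# ---------------------------------------------------------------------------
# low-level line handling


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt") as handle:
            yield from handle
    else:
        yield from source


def _split_fields(line: str) -> list[str]:
    # VCF is tab-delimited; whitespace-delimited fixtures are tolerated.
    if "\t" in line:
        return line.rstrip("\n").split("\t")
    return line.rstrip("\n").split()


def _parse_info(text: str, line_no: int) -> dict[str, Optional[str]]:
    if text in (".", ""):
        return {}
    info: dict[str, Optional[str]] = {}
    for item in text.split(";"):
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            info[key] = value
        else:
            info[item] = None
    return info


def _parse_gt(token: str) -> Optional[tuple[int, int]]:
    parts = token.replace("|", "/").split("/")
    if len(parts) != 2:
        return None
    try:
        return (int(parts[0]), int(parts[1]))
    except ValueError:
        return None  # "./." or half-missing -> missing genotype


def _parse_float(token: Optional[str]) -> Optional[float]:
    if token in (None, ".", ""):
        return None
    return float(token)  # type: ignore[arg-type]


def _parse_int(token: Optional[str]) -> Optional[int]:
    if token in (None, ".", ""):
        return None
    return int(token)  # type: ignore[arg-type]


def _fmt_num(value: Optional[float]) -> str:
    if value is None:
        return "."
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return format(value, "g")


class _OrderChecker:
    """Enforces contig-grouped, position-sorted record order."""

    def __init__(self) -> None:
        self.seen: list[str] = []
        self.last_pos: Optional[int] = None

    def check(self, contig: str, pos: int, line_no: Optional[int] = None) -> None:
        where = f" (line {line_no})" if line_no is not None else ""
        if not self.seen or self.seen[-1] != contig:
            if contig in self.seen:
                raise RecordOrderError(
                    f"contig {contig} revisited out of order{where}"
                )
            self.seen.append(contig)
            self.last_pos = pos
            return
        if self.last_pos is not None and pos < self.last_pos:
            raise RecordOrderError(
                f"{contig}:{pos} after {contig}:{self.last_pos}{where}"
            )
        self.last_pos = pos


# ---------------------------------------------------------------------------
# gVCF


def parse_gvcf(source: Source) -> list[GvcfRecord]:
    """Parse a gVCF stream into an ordered list of records.

    Every data line maps to exactly one :class:`GvcfRecord`.  A line with ALT
    ``.`` is a non-variant BLOCK whose end coordinate is taken from the END
    key (defaulting to the REF span for single-position reference calls).
    Raises :class:`VcfParseError` (with the line number) on malformed lines,
    :class:`InvalidRecordError` when END < POS, and :class:`RecordOrderError`
    on out-of-order records.
    """
    records: list[GvcfRecord] = []
    order = _OrderChecker()
    saw_header = False
    for line_no, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            saw_header = True
            continue
        if not saw_header:
            raise VcfParseError("data before header (#CHROM line missing)", line_no)
        fields = _split_fields(line)
        if len(fields) < 8:
            raise VcfParseError(f"expected >=8 columns, found {len(fields)}", line_no)
        contig, pos_s, id_s, ref, alt_s, qual_s, filt_s, info_s = fields[:8]
        try:
            pos = int(pos_s)
        except ValueError:
            raise VcfParseError(f"bad POS {pos_s!r}", line_no) from None
        if not ref or any(b not in "ACGTN" for b in ref.upper()):
            raise VcfParseError(f"bad REF {ref!r}", line_no)
        info = _parse_info(info_s, line_no)
        fmt: dict[str, str] = {}
        if len(fields) >= 10:
            keys = fields[8].split(":")
            values = fields[9].split(":")
            fmt = dict(zip(keys, values))
        if alt_s in (".", ""):
            kind = RecordKind.BLOCK
            alts: tuple[str, ...] = ()
        else:
            alts = tuple(alt_s.split(","))
            if any(a.startswith("<") for a in alts):
                raise VcfParseError(f"symbolic ALT unsupported: {alt_s}", line_no)
            kind = RecordKind.VARIANT
        try:
            end = _parse_int(info.get("END"))
            gqx = _parse_float(fmt.get("GQX", info.get("GQX")))
            dp = _parse_int(fmt.get("DP", info.get("DP")))
            min_dp = _parse_int(fmt.get("MIN_DP", info.get("MIN_DP")))
            qual = _parse_float(qual_s)
        except ValueError as exc:
            raise VcfParseError(str(exc), line_no) from None
        try:
            record = GvcfRecord(
                contig=contig,
                pos=pos,
                ref=ref,
                kind=kind,
                id=None if id_s == "." else id_s,
                alts=alts,
                qual=qual,
                filter=() if filt_s == "." else tuple(filt_s.split(";")),
                end=end,
                gt=_parse_gt(fmt["GT"]) if "GT" in fmt else None,
                gqx=gqx,
                dp=dp,
                min_dp=min_dp,
            )
        except InvalidRecordError as exc:
            raise InvalidRecordError(str(exc), line_no) from None
        order.check(contig, pos, line_no)
        records.append(record)
    return records


def write_gvcf(
    records: Sequence[GvcfRecord],
    stream: Optional[IO[str]] = None,
    *,
    sample: str = "SAMPLE",
    source: str = "evcfkit-synthetic",
) -> Optional[str]:
    """Serialize gVCF records; returns the text when no stream is given."""
    out = stream or io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write(f"##source={source}\n")
    out.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Block end">\n')
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write('##FORMAT=<ID=GQX,Number=1,Type=Float,Description="Genotype quality floor">\n')
    out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    out.write('##FORMAT=<ID=MIN_DP,Number=1,Type=Integer,Description="Minimum block depth">\n')
    for contig in dict.fromkeys(r.contig for r in records):
        out.write(f"##contig=<ID={contig}>\n")
    out.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
    )
    for rec in records:
        info = f"END={rec.end}" if rec.kind is RecordKind.BLOCK else "."
        gt = "./." if rec.gt is None else f"{rec.gt[0]}/{rec.gt[1]}"
        fmt_keys = ["GT", "GQX", "DP", "MIN_DP"]
        fmt_vals = [
            gt,
            _fmt_num(rec.gqx),
            _fmt_num(rec.dp),
            _fmt_num(rec.min_dp),
        ]
        if rec.min_dp is None:
            fmt_keys.pop()
            fmt_vals.pop()
        out.write(
            "\t".join(
                [
                    rec.contig,
                    str(rec.pos),
                    rec.id or ".",
                    rec.ref,
                    ",".join(rec.alts) or ".",
                    _fmt_num(rec.qual),
                    ";".join(rec.filter) or ".",
                    info,
                    ":".join(fmt_keys),
                    ":".join(fmt_vals),
                ]
            )
            + "\n"
        )
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None


# ---------------------------------------------------------------------------
# sites-only VCF


@dataclass
class SiteVcfResult:
    """Parsed sites-only VCF: records plus skip tally and significance labels."""

    records: list[SiteRecord]
    n_skipped: int = 0
    significance: dict[tuple[str, int, str], frozenset[str]] = field(default_factory=dict)


def parse_site_vcf(
    source: Source,
    *,
    freq_key: str = "CAF",
    significance_key: str = "CLNSIG",
) -> SiteVcfResult:
    """Parse a sites-only (dbSNP/ClinVar-style) VCF into site records.

    ``freq_key`` names the INFO key carrying comma-separated allele
    frequencies, reference first then one per ALT (dbSNP CAF convention).
    ``significance_key`` names the clinical-significance INFO key; its labels
    are returned per site.  Lines with ALT ``.`` carry no allele to genotype
    and are counted in ``n_skipped``.  A repeated (contig, pos, ref, rsid)
    key keeps the record but flags it as duplicate.
    """
    result = SiteVcfResult(records=[])
    seen: set[tuple[str, int, str, Optional[str]]] = set()
    order = _OrderChecker()
    for line_no, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = _split_fields(line)
        if len(fields) < 5:
            raise VcfParseError(f"expected >=5 columns, found {len(fields)}", line_no)
        contig, pos_s, id_s, ref, alt_s = fields[:5]
        info = _parse_info(fields[7], line_no) if len(fields) >= 8 else {}
        if not ref or ref == ".":
            raise VcfParseError("missing REF", line_no)
        if not alt_s:
            raise VcfParseError("missing ALT", line_no)
        if alt_s == ".":
            result.n_skipped += 1
            continue
        try:
            pos = int(pos_s)
        except ValueError:
            raise VcfParseError(f"bad POS {pos_s!r}", line_no) from None
        alts = tuple(alt_s.split(","))
        alt_freqs: tuple[Optional[float], ...] = ()
        raw_freqs = info.get(freq_key)
        if raw_freqs:
            tokens = raw_freqs.split(",")
            # reference frequency first, then one per ALT
            per_alt = tokens[1 : 1 + len(alts)]
            alt_freqs = tuple(
                None if t in (".", "") else float(t) for t in per_alt
            )
            if len(alt_freqs) < len(alts):
                alt_freqs = alt_freqs + (None,) * (len(alts) - len(alt_freqs))
        rsid = None if id_s == "." else id_s
        key = (contig, pos, ref, rsid)
        record = SiteRecord(
            contig=contig,
            pos=pos,
            ref=ref,
            alts=alts,
            rsid=rsid,
            alt_freqs=alt_freqs,
            duplicate=key in seen,
        )
        seen.add(key)
        order.check(contig, pos, line_no)
        result.records.append(record)
        raw_sig = info.get(significance_key)
        if raw_sig:
            result.significance[record.key] = frozenset(raw_sig.split(","))
    return result


def write_site_vcf(
    sites: Sequence[SiteRecord],
    stream: Optional[IO[str]] = None,
    *,
    freq_key: str = "CAF",
    significance: Optional[Mapping[tuple[str, int, str], Iterable[str]]] = None,
    significance_key: str = "CLNSIG",
) -> Optional[str]:
    """Serialize a sites-only VCF (frequencies in dbSNP CAF layout)."""
    out = stream or io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write(
        f'##INFO=<ID={freq_key},Number=.,Type=Float,Description="Allele frequencies, REF first">\n'
    )
    out.write(
        f'##INFO=<ID={significance_key},Number=.,Type=String,Description="Clinical significance">\n'
    )
    for contig in dict.fromkeys(s.contig for s in sites):
        out.write(f"##contig=<ID={contig}>\n")
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for site in sites:
        info_parts = []
        if any(q is not None for q in site.alt_freqs):
            total_alt = sum(q for q in site.alt_freqs if q is not None)
            tokens = [format(max(0.0, 1.0 - total_alt), "g")] + [
                "." if q is None else format(q, "g") for q in site.alt_freqs
            ]
            info_parts.append(f"{freq_key}={','.join(tokens)}")
        if significance and site.key in significance:
            labels = ",".join(sorted(significance[site.key]))
            info_parts.append(f"{significance_key}={labels}")
        out.write(
            "\t".join(
                [
                    site.contig,
                    str(site.pos),
                    site.rsid or ".",
                    site.ref,
                    ",".join(site.alts),
                    ".",
                    ".",
                    ";".join(info_parts) or ".",
                ]
            )
            + "\n"
        )
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None


# ---------------------------------------------------------------------------
# eVCF


def write_evcf(
    records: Sequence[EvcfRecord],
    meta: EvcfHeaderMeta,
    stream: Optional[IO[str]] = None,
) -> Optional[str]:
    """Serialize eVCF records with catalog provenance in the header.

    Raises :class:`RecordOrderError` on unsorted input,
    :class:`SerializationError` when a record uses an undeclared INFO key or
    when catalog records are present but the catalog name/version is empty.
    """
    declared = {k.id: k for k in meta.extra_info_keys}
    order = _OrderChecker()
    has_catalog_records = False
    for rec in records:
        order.check(rec.contig, rec.pos)
        for key in rec.info:
            if key not in declared:
                raise SerializationError(
                    f"INFO key {key!r} at {rec.contig}:{rec.pos} not declared in header"
                )
        if rec.is_catalog_site:
            has_catalog_records = True
    if has_catalog_records and not (meta.catalog_name and meta.catalog_version):
        raise SerializationError(
            "catalog records present but catalog name/version missing from header meta"
        )
    out = stream or io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write("##source=evcfkit\n")
    if meta.catalog_name or meta.catalog_version:
        out.write(
            f"##siteCatalog=<name={meta.catalog_name},version={meta.catalog_version}>\n"
        )
    if meta.source_gvcf:
        out.write(f"##sourceGvcf={meta.source_gvcf}\n")
    if meta.policy:
        out.write(f"##evcfPolicy=<{meta.policy}>\n")
    for key in meta.extra_info_keys:
        out.write(key.header_line() + "\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write('##FORMAT=<ID=GQX,Number=1,Type=Float,Description="Genotype quality floor">\n')
    out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    for contig in dict.fromkeys(r.contig for r in records):
        out.write(f"##contig=<ID={contig}>\n")
    out.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + meta.sample + "\n"
    )
    for rec in records:
        out.write(_format_evcf_line(rec, declared) + "\n")
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None


def _format_evcf_line(rec: EvcfRecord, declared: Mapping[str, InfoKey]) -> str:
    info_parts: list[str] = []
    for key, value in rec.info.items():
        decl = declared[key]
        if decl.type == "Flag":
            if value:
                info_parts.append(key)
        elif isinstance(value, (tuple, list)):
            rendered = ",".join("." if v is None else _fmt_num_or_str(v) for v in value)
            if rendered:
                info_parts.append(f"{key}={rendered}")
        else:
            info_parts.append(f"{key}={_fmt_num_or_str(value)}")
    gt = "./." if rec.gt is None else f"{rec.gt[0]}/{rec.gt[1]}"
    return "\t".join(
        [
            rec.contig,
            str(rec.pos),
            rec.id or ".",
            rec.ref,
            ",".join(rec.alts) or ".",
            _fmt_num(rec.qual),
            ";".join(rec.filter) or ".",
            ";".join(info_parts) or ".",
            "GT:GQX:DP",
            ":".join([gt, _fmt_num(rec.gqx), _fmt_num(rec.dp)]),
        ]
    )


def _fmt_num_or_str(value) -> str:
    if isinstance(value, (int, float)):
        return _fmt_num(float(value))
    return str(value)


def parse_evcf(source: Source) -> tuple[EvcfHeaderMeta, list[EvcfRecord]]:
    """Parse an eVCF file back into header metadata and records.

    INFO values are typed from the header declarations: flags become ``True``,
    list-valued keys become tuples (Float entries parsed, ``.`` to ``None``).
    """
    meta = EvcfHeaderMeta(extra_info_keys=())
    declared: dict[str, InfoKey] = {}
    records: list[EvcfRecord] = []
    order = _OrderChecker()
    keys_acc: list[InfoKey] = []
    for line_no, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##siteCatalog=<") and line.endswith(">"):
            body = line[len("##siteCatalog=<") : -1]
            for part in body.split(","):
                k, _, v = part.partition("=")
                if k == "name":
                    meta.catalog_name = v
                elif k == "version":
                    meta.catalog_version = v
            continue
        if line.startswith("##sourceGvcf="):
            meta.source_gvcf = line.partition("=")[2]
            continue
        if line.startswith("##evcfPolicy=<") and line.endswith(">"):
            meta.policy = line[len("##evcfPolicy=<") : -1]
            continue
        if line.startswith("##INFO=<") and line.endswith(">"):
            attrs = _parse_header_attrs(line[len("##INFO=<") : -1])
            key = InfoKey(
                attrs.get("ID", ""),
                attrs.get("Number", "."),
                attrs.get("Type", "String"),
                attrs.get("Description", "").strip('"'),
            )
            declared[key.id] = key
            keys_acc.append(key)
            continue
        if line.startswith("#CHROM"):
            cols = _split_fields(line)
            if len(cols) >= 10:
                meta.sample = cols[9]
            continue
        if line.startswith("#"):
            continue
        fields = _split_fields(line)
        if len(fields) < 8:
            raise VcfParseError(f"expected >=8 columns, found {len(fields)}", line_no)
        contig, pos_s, id_s, ref, alt_s, qual_s, filt_s, info_s = fields[:8]
        fmt: dict[str, str] = {}
        if len(fields) >= 10:
            fmt = dict(zip(fields[8].split(":"), fields[9].split(":")))
        info: dict = {}
        for key, value in _parse_info(info_s, line_no).items():
            decl = declared.get(key)
            if decl is None:
                raise VcfParseError(f"undeclared INFO key {key!r}", line_no)
            if decl.type == "Flag":
                info[key] = True
            elif decl.number == ".":
                tokens = (value or "").split(",")
                if decl.type == "Float":
                    info[key] = tuple(
                        None if t == "." else float(t) for t in tokens
                    )
                else:
                    info[key] = tuple(tokens)
            elif decl.type == "Integer":
                info[key] = _parse_int(value)
            elif decl.type == "Float":
                info[key] = _parse_float(value)
            else:
                info[key] = value
        try:
            pos = int(pos_s)
        except ValueError:
            raise VcfParseError(f"bad POS {pos_s!r}", line_no) from None
        record = EvcfRecord(
            contig=contig,
            pos=pos,
            ref=ref,
            alts=() if alt_s == "." else tuple(alt_s.split(",")),
            id=None if id_s == "." else id_s,
            qual=_parse_float(qual_s),
            filter=() if filt_s == "." else tuple(filt_s.split(";")),
            info=info,
            gt=_parse_gt(fmt["GT"]) if "GT" in fmt else None,
            gqx=_parse_float(fmt.get("GQX")),
            dp=_parse_int(fmt.get("DP")),
        )
        order.check(contig, pos, line_no)
        records.append(record)
    meta.extra_info_keys = tuple(keys_acc)
    return meta, records


def _parse_header_attrs(body: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    in_quotes = False
    token = ""
    parts: list[str] = []
    for ch in body:
        if ch == '"':
            in_quotes = not in_quotes
            token += ch
        elif ch == "," and not in_quotes:
            parts.append(token)
            token = ""
        else:
            token += ch
    if token:
        parts.append(token)
    for part in parts:
        k, _, v = part.partition("=")
        attrs[k] = v
    return attrs


# ---------------------------------------------------------------------------
# array reports


@dataclass
class ArrayReportColumns:
    """Column names of the five-column array-report TSV (configurable)."""

    marker: str = "marker_id"
    chrom: str = "contig"
    pos: str = "pos"
    allele_a: str = "allele_a"
    allele_b: str = "allele_b"


_ARRAY_MISSING = {"-", "--", ""}


def parse_array_report(
    source: Source,
    expected_sites: Mapping[str, SiteRecord],
    *,
    columns: Optional[ArrayReportColumns] = None,
) -> list[ArrayGenotype]:
    """Parse a genotyping-array report TSV.

    ``-``/``--`` alleles become missing (array no-call).  A marker absent
    from ``expected_sites`` is retained but flagged ``matched=False`` so the
    allele-normalization step can skip it.  Any allele outside {A, C, G, T}
    other than the missing tokens raises :class:`ArrayReportError`.
    """
    cols = columns or ArrayReportColumns()
    if isinstance(source, (str, Path)):
        frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for name in (cols.marker, cols.chrom, cols.pos, cols.allele_a, cols.allele_b):
        if name not in frame.columns:
            raise ArrayReportError(f"array report is missing column {name!r}")
    out: list[ArrayGenotype] = []
    for row in frame.to_dict("records"):
        marker = row[cols.marker]
        a = row[cols.allele_a].strip()
        b = row[cols.allele_b].strip()
        allele_a = None if a in _ARRAY_MISSING else a.upper()
        allele_b = None if b in _ARRAY_MISSING else b.upper()
        out.append(
            ArrayGenotype(
                marker_id=marker,
                contig=row[cols.chrom],
                pos=int(row[cols.pos]),
                allele_a=allele_a,
                allele_b=allele_b,
                matched=marker in expected_sites,
            )
        )
    return out


def write_array_report(
    genotypes: Sequence[ArrayGenotype],
    stream: Optional[IO[str]] = None,
    *,
    columns: Optional[ArrayReportColumns] = None,
) -> Optional[str]:
    """Serialize array genotypes as the five-column TSV dialect."""
    cols = columns or ArrayReportColumns()
    out = stream or io.StringIO()
    out.write(
        "\t".join([cols.marker, cols.chrom, cols.pos, cols.allele_a, cols.allele_b]) + "\n"
    )
    for g in genotypes:
        out.write(
            "\t".join(
                [
                    g.marker_id,
                    g.contig,
                    str(g.pos),
                    g.allele_a or "-",
                    g.allele_b or "-",
                ]
            )
            + "\n"
        )
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None


# ---------------------------------------------------------------------------
# annotation-table export


class AnnotationRow(NamedTuple):
    """One row of the annotation-table dialect (1-based inclusive coordinates)."""

    contig: str
    start: int
    end: int
    reference_observed: str
    sample_observed: str


def export_annotation_table(
    records: Iterable[EvcfRecord], *, include_nocalls: bool = False
) -> tuple[list[AnnotationRow], int]:
    """Convert eVCF records to annotation-table rows.

    SNVs keep their position; indels are left-anchor-trimmed: a deletion REF
    ``AG`` ALT ``A`` becomes the deleted base ``G`` at pos+1 with sample
    allele ``-``, an insertion REF ``A`` ALT ``AG`` becomes ``-`` to ``G`` at
    the anchor base.  Hom-ref catalog records emit the reference allele as
    the sample allele.  Records with a missing genotype are skipped and
    tallied unless ``include_nocalls`` (then emitted with sample allele
    ``.``).  Returns ``(rows, n_skipped)``.
    """
    rows: list[AnnotationRow] = []
    n_skipped = 0
    for rec in records:
        if rec.gt is None:
            if include_nocalls:
                end = rec.pos + len(rec.ref) - 1
                rows.append(AnnotationRow(rec.contig, rec.pos, end, rec.ref, "."))
            else:
                n_skipped += 1
            continue
        alt_indices = sorted({i for i in rec.gt if i > 0})
        if not alt_indices:
            end = rec.pos + len(rec.ref) - 1
            rows.append(AnnotationRow(rec.contig, rec.pos, end, rec.ref, rec.ref))
            continue
        for idx in alt_indices:
            alt = rec.alts[idx - 1]
            rows.append(_annotation_row(rec.contig, rec.pos, rec.ref, alt))
    return rows, n_skipped


def _annotation_row(contig: str, pos: int, ref: str, alt: str) -> AnnotationRow:
    # trim the longest common prefix (left anchor)
    trim = 0
    while trim < len(ref) and trim < len(alt) and ref[trim] == alt[trim]:
        trim += 1
    ref_rest = ref[trim:]
    alt_rest = alt[trim:]
    if ref_rest and alt_rest:
        start = pos + trim
        return AnnotationRow(contig, start, start + len(ref_rest) - 1, ref_rest, alt_rest)
    if ref_rest:  # deletion
        start = pos + trim
        return AnnotationRow(contig, start, start + len(ref_rest) - 1, ref_rest, "-")
    # insertion: anchored at the last shared base
    anchor = pos + trim - 1
    return AnnotationRow(contig, anchor, anchor, "-", alt_rest)
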