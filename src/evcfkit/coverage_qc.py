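"""Per-base coverage QC: gap detection, region coverage fractions, GC/AT
sequence-context classification, and binomial coverage thinning.

A base is *covered* when its read depth, alignment (mapping) quality and
basecall quality all meet their thresholds (≥ 5 / ≥ 10 / ≥ 10 by default).
A *gap* is a maximal run of non-covered bases longer than 10 bp.  Windows of
high (≥75%) and extreme (≥85%) GC content and runs of ≥30 bp of repeated AT
dinucleotides mark the sequence contexts where short-read coverage
characteristically degrades.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from evcfkit.errors import EvcfKitError, RegionCoverageError


@dataclass
class CoverageProfile:
    """Aligned per-base depth / mapping-quality / basecall-quality arrays.

    ``start`` is the 1-based coordinate of the first array element.
    """

    contig: str
    start: int
    depth: np.ndarray
    mapq: np.ndarray
    baseq: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.mapq = np.asarray(self.mapq, dtype=float)
        self.baseq = np.asarray(self.baseq, dtype=float)
        if not (len(self.depth) == len(self.mapq) == len(self.baseq)):
            raise EvcfKitError("coverage profile arrays must have equal length")
        if (self.depth < 0).any() or (self.mapq < 0).any() or (self.baseq < 0).any():
            raise EvcfKitError("coverage profile arrays must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def end(self) -> int:
        return self.start + len(self.depth) - 1


@dataclass(frozen=True)
class QcThresholds:
    """Coverage and sequence-context thresholds.

    ``min_gap_len`` = 11 encodes "runs longer than 10 bp".  ``inclusive``
    selects ≥-comparisons for the three coverage criteria (the alternative
    is strict >).  ``gap_logic`` controls what makes a base a gap base:
    ``"any"`` — any criterion failing (complement of covered, default) —
    or ``"all"`` — all three criteria failing simultaneously.
    """

    min_depth: float = 5
    min_mapq: float = 10
    min_baseq: float = 10
    min_gap_len: int = 11
    gc_high: float = 0.75
    gc_extreme: float = 0.85
    gc_window: int = 100
    at_run_min: int = 30
    inclusive: bool = True
    gap_logic: str = "any"

    def __post_init__(self) -> None:
        if not (0 <= self.gc_high <= self.gc_extreme <= 1):
            raise ValueError("need 0 <= gc_high <= gc_extreme <= 1")
        if self.min_gap_len < 1:
            raise ValueError("min_gap_len must be >= 1")
        if self.gap_logic not in ("any", "all"):
            raise ValueError("gap_logic must be 'any' or 'all'")

    def covered_mask(self, profile: CoverageProfile) -> np.ndarray:
        if self.inclusive:
            return (
                (profile.depth >= self.min_depth)
                & (profile.mapq >= self.min_mapq)
                & (profile.baseq >= self.min_baseq)
            )
        return (
            (profile.depth > self.min_depth)
            & (profile.mapq > self.min_mapq)
            & (profile.baseq > self.min_baseq)
        )

    def gap_mask(self, profile: CoverageProfile) -> np.ndarray:
        if self.gap_logic == "any":
            return ~self.covered_mask(profile)
        if self.inclusive:
            return (
                (profile.depth < self.min_depth)
                & (profile.mapq < self.min_mapq)
                & (profile.baseq < self.min_baseq)
            )
        return (
            (profile.depth <= self.min_depth)
            & (profile.mapq <= self.min_mapq)
            & (profile.baseq <= self.min_baseq)
        )


@dataclass
class GapInterval:
    """A maximal low-quality run, 1-based inclusive."""

    contig: str
    start: int
    end: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start_idx, end_idx) inclusive, 0-based."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_gaps(
    profile: CoverageProfile, t: QcThresholds = QcThresholds()
) -> list[GapInterval]:
    """Find maximal gap runs longer than ``min_gap_len - 1`` bases.

    Returned sorted and non-overlapping; a run of exactly 10 low-quality
    bases is not a gap under the defaults ("longer than 10 bp").
    """
    if len(profile) == 0:
        raise EvcfKitError("coverage profile is empty")
    mask = t.gap_mask(profile)
    gaps: list[GapInterval] = []
    for i0, i1 in _runs(mask):
        if i1 - i0 + 1 >= t.min_gap_len:
            gaps.append(
                GapInterval(
                    contig=profile.contig,
                    start=profile.start + i0,
                    end=profile.start + i1,
                    mean_depth=float(profile.depth[i0 : i1 + 1].mean()),
                )
            )
    return gaps


Region = tuple[str, int, int]  # contig, start, end — 1-based inclusive


def coverage_fraction(
    profiles: Union[CoverageProfile, Sequence[CoverageProfile]],
    regions: Sequence[Region],
    t: QcThresholds = QcThresholds(),
) -> float:
    """Fraction of region bases that are covered.

    Every region must lie inside one of the profiles; a region outside all
    profiles raises :class:`RegionCoverageError` naming it.
    """
    if isinstance(profiles, CoverageProfile):
        profiles = [profiles]
    if not regions:
        raise RegionCoverageError("empty region list")
    by_contig: dict[str, list[CoverageProfile]] = {}
    for p in profiles:
        by_contig.setdefault(p.contig, []).append(p)
    covered = 0
    total = 0
    for contig, start, end in regions:
        if end < start:
            raise RegionCoverageError(f"region {contig}:{start}-{end} has end < start")
        hit = None
        for p in by_contig.get(contig, ()):
            if p.start <= start and end <= p.end:
                hit = p
                break
        if hit is None:
            raise RegionCoverageError(
                f"region {contig}:{start}-{end} lies outside all coverage profiles"
            )
        mask = t.covered_mask(hit)
        i0 = start - hit.start
        i1 = end - hit.start + 1
        covered += int(mask[i0:i1].sum())
        total += end - start + 1
    return covered / total


class WindowClass(Enum):
    NORMAL = "normal"
    HIGH_GC = "high_gc"
    EXTREME_GC = "extreme_gc"


@dataclass
class GcWindow:
    """One tiled GC-content window, 1-based inclusive."""

    start: int
    end: int
    gc_fraction: Optional[float]
    window_class: WindowClass


def classify_gc_windows(
    sequence: str, t: QcThresholds = QcThresholds()
) -> list[GcWindow]:
    """Classify non-overlapping ``gc_window``-bp windows by GC content.

    N bases are excluded from both numerator and denominator; a window of
    only Ns has undefined GC and is classed NORMAL.  The trailing partial
    window is skipped.  Raises on characters outside ACGTN.
    """
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise EvcfKitError(f"sequence contains non-ACGTN characters: {sorted(invalid)}")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    is_n = arr == b"N"
    out: list[GcWindow] = []
    w = t.gc_window
    for start in range(0, len(seq) - w + 1, w):
        gc = int(is_gc[start : start + w].sum())
        informative = w - int(is_n[start : start + w].sum())
        if informative == 0:
            out.append(GcWindow(start + 1, start + w, None, WindowClass.NORMAL))
            continue
        frac = gc / informative
        if frac >= t.gc_extreme:
            cls = WindowClass.EXTREME_GC
        elif frac >= t.gc_high:
            cls = WindowClass.HIGH_GC
        else:
            cls = WindowClass.NORMAL
        out.append(GcWindow(start + 1, start + w, frac, cls))
    return out


def find_at_runs(
    sequence: str, t: QcThresholds = QcThresholds()
) -> list[tuple[int, int]]:
    """Maximal runs of alternating AT dinucleotides of length ≥ ``at_run_min``.

    A run is a stretch over {A, T} in which adjacent bases always differ
    (ATAT… or TATA…); homopolymers do not qualify.  Intervals are 1-based
    inclusive.
    """
    seq = sequence.upper()
    out: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] not in "AT":
            i += 1
            continue
        j = i
        while j + 1 < n and seq[j + 1] in "AT" and seq[j + 1] != seq[j]:
            j += 1
        if j - i + 1 >= t.at_run_min:
            out.append((i + 1, j + 1))
        i = j + 1
    return out


def thin_coverage(
    profile: CoverageProfile, target_mean: float, seed: int
) -> CoverageProfile:
    """Binomially thin per-base depths down to a target mean coverage.

    Each depth ``d`` is replaced by a Binomial(d, target/current) draw,
    emulating sub-sampling of the read set while leaving quality summaries
    untouched.  Deterministic for a fixed seed; zero-depth bases stay zero.
    """
    current = float(profile.depth.mean())
    if target_mean > current:
        raise EvcfKitError(
            f"target mean {target_mean:g} exceeds current mean {current:g}"
        )
    p = 1.0 if current == 0 else target_mean / current
    if p >= 1.0:
        new_depth = profile.depth.copy()
    else:
        rng = np.random.default_rng(seed)
        new_depth = rng.binomial(profile.depth.astype(np.int64), p)
    return CoverageProfile(
        contig=profile.contig,
        start=profile.start,
        depth=new_depth,
        mapq=profile.mapq.copy(),
        baseq=profile.baseq.copy(),
    )


# ---------------------------------------------------------------------------
# file input


def read_bed(source: Union[str, Path, IO[str], Iterable[str]]) -> list[Region]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            lines = handle.readlines()
    else:
        lines = list(source)
    regions: list[Region] = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        regions.append((contig, start0 + 1, end0))
    return regions


def read_profile_tsv(source: Union[str, Path, IO[str]]) -> list[CoverageProfile]:
    """Read per-base profiles from a TSV with columns contig, pos, depth, mapq, baseq.

    Positions must be contiguous within each contig.
    """
    frame = pd.read_csv(source, sep="\t")
    needed = {"contig", "pos", "depth", "mapq", "baseq"}
    if not needed.issubset(frame.columns):
        raise EvcfKitError(f"profile TSV must have columns {sorted(needed)}")
    profiles: list[CoverageProfile] = []
    for contig, group in frame.groupby("contig", sort=False):
        group = group.sort_values("pos")
        pos = group["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) == 1).all():
            raise EvcfKitError(f"profile positions on {contig} are not contiguous")
        profiles.append(
            CoverageProfile(
                contig=str(contig),
                start=int(pos[0]),
                depth=group["depth"].to_numpy(dtype=np.int64),
                mapq=group["mapq"].to_numpy(dtype=float),
                baseq=group["baseq"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_profile_tsv(
    profiles: Union[CoverageProfile, Sequence[CoverageProfile]],
    stream: Optional[IO[str]] = None,
) -> Optional[str]:
    """Serialize profiles back to the five-column TSV."""
    import io as _io

    if isinstance(profiles, CoverageProfile):
        profiles = [profiles]
    out = stream or _io.StringIO()
    out.write("contig\tpos\tdepth\tmapq\tbaseq\n")
    for p in profiles:
        for i in range(len(p)):
            out.write(
                f"{p.contig}\t{p.start + i}\t{int(p.depth[i])}\t{p.mapq[i]:g}\t{p.baseq[i]:g}\n"
            )
    if stream is None:
        return out.getvalue()  # type: ignore[union-attr]
    return None
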