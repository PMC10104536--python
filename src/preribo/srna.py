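"""Strand-specific small-RNA mapping and quantification on the rDNA unit.

Reads of 18-40 nt are mapped ungapped and end-to-end against the sense
strand and the reverse complement of the single 45S rDNA reference.  A read
matching equally well at several positions receives fractional weight 1/n
at each — deterministic, unlike random placement.  Quantification reports
reads per million (RPM) per (subregion, strand, length class); 21-nt and
22-nt siRNAs are first-class size classes, everything else aggregates into
``other``.  Reads straddling the 18S/ITS1 boundary form their own linker
class (``18S-ITS1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reference import REGION_ORDER, RdnaReference, revcomp

MATRIX_REGIONS = ("NTS", "5'ETS", "18S", "18S-ITS1", "ITS1", "5.8S", "ITS2", "25S", "3'ETS")
LENGTH_CLASSES = ("21", "22", "other")


@dataclass(frozen=True)
class SrnaAlignment:
    read_id: str
    ref_start: int
    ref_end: int
    strand: str
    length: int
    mismatches: int
    weight: float = 1.0


@dataclass
class MappingStats:
    mapped: int = 0
    unmapped: int = 0
    out_of_range: int = 0
    malformed: int = 0

    @property
    def total(self) -> int:
        return self.mapped + self.unmapped + self.out_of_range + self.malformed


def _exact_hits(ref: str, read: str) -> List[int]:
    hits = []
    i = ref.find(read)
    while i != -1:
        hits.append(i)
        i = ref.find(read, i + 1)
    return hits


def _mismatch_hits(ref: str, read: str, max_mm: int) -> List[Tuple[int, int]]:
    """All-positions scan returning (position, mismatches) at the minimal
    mismatch count <= max_mm.  Used only when mismatches are allowed."""
    n, m = len(ref), len(read)
    best = max_mm + 1
    hits: List[Tuple[int, int]] = []
    for i in range(n - m + 1):
        mm = 0
        window = ref[i : i + m]
        if window == read:
            mm = 0
        else:
            for a, b in zip(window, read):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm > max_mm:
                continue
        if mm < best:
            best = mm
            hits = [(i, mm)]
        elif mm == best:
            hits.append((i, mm))
    return hits


def map_srna(
    reads: Iterable[Tuple[str, str]],
    ref: RdnaReference,
    max_mismatch: int = 0,
    length_range: Tuple[int, int] = (18, 40),
) -> Tuple[List[SrnaAlignment], MappingStats]:
    """Map small-RNA reads to both strands of the rDNA reference.

    Returns the alignments (fractionally weighted for multi-mappers) and
    the mapping statistics.  Only reads inside ``length_range`` are mapped.
    """
    fwd = ref.sequence
    rev = revcomp(fwd)
    n = len(fwd)
    alignments: List[SrnaAlignment] = []
    stats = MappingStats()
    lo, hi = length_range
    for read_id, seq in reads:
        seq = seq.upper()
        if not seq or set(seq) - set("ACGTN"):
            stats.malformed += 1
            continue
        m = len(seq)
        if not (lo <= m <= hi):
            stats.out_of_range += 1
            continue
        if max_mismatch == 0:
            hits = [(p, 0, "+") for p in _exact_hits(fwd, seq)]
            hits += [(p, 0, "-") for p in _exact_hits(rev, seq)]
        else:
            hits = [(p, mm, "+") for p, mm in _mismatch_hits(fwd, seq, max_mismatch)]
            hits += [(p, mm, "-") for p, mm in _mismatch_hits(rev, seq, max_mismatch)]
            if hits:
                best = min(mm for _, mm, _ in hits)
                hits = [h for h in hits if h[1] == best]
        if not hits:
            stats.unmapped += 1
            continue
        stats.mapped += 1
        w = 1.0 / len(hits)
        for p, mm, strand in hits:
            # hits on the reverse complement are reported in forward
            # reference coordinates
            start = p if strand == "+" else n - p - m
            alignments.append(
                SrnaAlignment(
                    read_id=read_id,
                    ref_start=start,
                    ref_end=start + m,
                    strand=strand,
                    length=m,
                    mismatches=mm,
                    weight=w,
                )
            )
    return alignments, stats


def coverage_track(
    alignments: Sequence[SrnaAlignment],
    ref_len: int,
    lengths: Iterable[int] = (21, 22),
) -> Dict[str, np.ndarray]:
    """Per-position weighted coverage for the requested read lengths,
    one track per strand."""
    wanted = set(lengths)
    tracks = {"+": np.zeros(ref_len), "-": np.zeros(ref_len)}
    for a in alignments:
        if a.length in wanted:
            tracks[a.strand][a.ref_start : a.ref_end] += a.weight
    return tracks


def track_to_bedgraph(track: np.ndarray, ref_name: str) -> pd.DataFrame:
    """Run-length-encode a coverage track into bedGraph-style rows
    (0-based half-open, per the bedGraph convention)."""
    rows = []
    if len(track):
        change = np.flatnonzero(np.diff(track)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(track)]))
        for s, e in zip(starts, ends):
            v = track[s]
            if v != 0:
                rows.append({"chrom": ref_name, "start": int(s), "end": int(e), "value": float(v)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def length_class(length: int) -> str:
    if length == 21:
        return "21"
    if length == 22:
        return "22"
    return "other"


def assign_region(a: SrnaAlignment, ref: RdnaReference) -> Optional[str]:
    """Region assignment for one alignment.

    A read overlapping both 18S and ITS1 is the linker class ``18S-ITS1``;
    otherwise the read belongs to the region covering at least 50% of its
    length (ties resolved toward the larger overlap, then the upstream
    region).  Reads covering no region by 50% are unassigned.
    """
    s18 = ref.subregions["18S"]
    its1 = ref.subregions["ITS1"]
    if s18.overlap(a.ref_start, a.ref_end) > 0 and its1.overlap(a.ref_start, a.ref_end) > 0:
        return "18S-ITS1"
    best_region, best_ov = None, 0
    for region in REGION_ORDER:
        ov = ref.subregions[region].overlap(a.ref_start, a.ref_end)
        if ov > best_ov:
            best_region, best_ov = region, ov
    if best_ov * 2 >= a.length:
        return best_region
    return None


@dataclass
class RegionMatrix:
    """RPM per (region, strand, length class) for one library."""

    library_id: str
    total_for_rpm: int
    rpm: pd.DataFrame  # index (region, strand, length_class), column "rpm"
    unassigned_weight: float = 0.0

    def cell(self, region: str, strand: str, lclass: str) -> float:
        return float(self.rpm.loc[(region, strand, lclass), "rpm"])


def _empty_matrix_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [MATRIX_REGIONS, ("+", "-"), LENGTH_CLASSES],
        names=["region", "strand", "length_class"],
    )


def region_rpm(
    alignments: Sequence[SrnaAlignment],
    ref: RdnaReference,
    total_for_rpm: int,
    library_id: str = "",
) -> RegionMatrix:
    """Reads-per-million matrix over (region, strand, length class).

    ``total_for_rpm`` is the library-size denominator — by default the
    caller passes the number of reads that passed the length filter; a
    genome-mapped total may be supplied instead.
    """
    if total_for_rpm <= 0:
        raise ValueError("total_for_rpm must be positive")
    counts: Dict[Tuple[str, str, str], float] = {}
    unassigned = 0.0
    for a in alignments:
        region = assign_region(a, ref)
        if region is None:
            unassigned += a.weight
            continue
        key = (region, a.strand, length_class(a.length))
        counts[key] = counts.get(key, 0.0) + a.weight
    idx = _empty_matrix_index()
    values = [1e6 * counts.get(key, 0.0) / total_for_rpm for key in idx]
    return RegionMatrix(
        library_id=library_id,
        total_for_rpm=total_for_rpm,
        rpm=pd.DataFrame({"rpm": values}, index=idx),
        unassigned_weight=unassigned,
    )


def fold_change_matrix(
    mut: RegionMatrix,
    wt: RegionMatrix,
    pseudocount_rpm: float = 1.0,
) -> pd.DataFrame:
    """Pseudocounted RPM fold change, mutant over wild type, per cell.

    Returns a table with ``fc`` and ``log2_fc`` columns on the shared
    (region, strand, length class) index.
    """
    if not mut.rpm.index.equals(wt.rpm.index):
        raise ValueError("region matrices have different cell structure")
    c = pseudocount_rpm
    fc = (mut.rpm["rpm"] + c) / (wt.rpm["rpm"] + c)
    return pd.DataFrame({"fc": fc, "log2_fc": np.log2(fc)})
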