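"""Aggregation of junction calls into end profiles and group statistics.

The central normalization follows the END-seq convention: counts of
precursor species (3' ends downstream of D, up to A2) are expressed
relative to mature 18S rRNA, defined as tail-free reads whose 3' end maps
exactly to the D site.  D-ending reads that carry a nontemplated tail are
reported in the tail tables but excluded from the mature denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .endseq import JunctionCall, Species, Status, classify_species
from .reference import RdnaReference


def tail_composition_class(tail: str) -> str:
    """Composition class of a tail: 'A', 'U', 'G', 'C' when homopolymeric
    (U is stored as T in sequence space), else 'mixed'."""
    bases = set(tail)
    if len(bases) == 1:
        b = next(iter(bases))
        return "U" if b == "T" else b
    return "mixed"


@dataclass
class EndProfile:
    """Per-library 3'-end counts keyed by offset from the D site."""

    library_id: str
    genotype: str = ""
    fraction: str = "Total"
    replicate: int = 1
    a2_offset: int = 0
    end_counts: Dict[int, int] = field(default_factory=dict)
    tail_counts: Dict[Tuple[int, int, str], int] = field(default_factory=dict)
    mature_count: int = 0
    flags: List[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.end_counts.values())


def build_profile(
    calls: Iterable[JunctionCall],
    ref: RdnaReference,
    library_id: str,
    genotype: str = "",
    fraction: str = "Total",
    replicate: int = 1,
) -> EndProfile:
    """Tally RESOLVED, P2-passing calls into an :class:`EndProfile`.

    Aggregation is order-independent (sorted keys); duplicate read ids are
    an error because deduplication is assumed upstream.
    """
    profile = EndProfile(
        library_id=library_id,
        genotype=genotype,
        fraction=fraction,
        replicate=replicate,
        a2_offset=ref.a2_offset,
    )
    seen = set()
    for call in calls:
        if call.status is not Status.RESOLVED:
            continue
        if call.read_id in seen:
            raise ValueError(f"duplicated read_id {call.read_id!r}")
        seen.add(call.read_id)
        ofs = ref.offset_from_d(call.three_prime_pos)
        profile.end_counts[ofs] = profile.end_counts.get(ofs, 0) + 1
        if call.tail_seq:
            key = (ofs, call.tail_len, tail_composition_class(call.tail_seq))
            profile.tail_counts[key] = profile.tail_counts.get(key, 0) + 1
        elif ofs == 0:
            profile.mature_count += 1
    profile.end_counts = dict(sorted(profile.end_counts.items()))
    profile.tail_counts = dict(sorted(profile.tail_counts.items()))
    if profile.mature_count == 0:
        profile.flags.append("no_mature_reads")
    return profile


def normalize_to_mature(profile: EndProfile) -> Dict[int, float]:
    """Relative abundance of each 3'-end offset versus mature 18S.

    Returns NaN values (and flags the profile) when the library has no
    tail-free D-ending reads — never a silent division by zero.
    """
    if profile.mature_count == 0:
        if "no_mature_reads" not in profile.flags:
            profile.flags.append("no_mature_reads")
        return {ofs: math.nan for ofs in profile.end_counts}
    m = profile.mature_count
    return {ofs: c / m for ofs, c in profile.end_counts.items()}


def pre18s_ratio(profile: EndProfile) -> float:
    """Percent ratio of precursor (0 < offset <= A2-D) to mature 18S reads.

    Ends upstream of D (degradation products) and beyond A2 do not enter
    the ratio.
    """
    if profile.mature_count == 0:
        return math.nan
    pre = sum(
        c for ofs, c in profile.end_counts.items() if 0 < ofs <= profile.a2_offset
    )
    return 100.0 * pre / profile.mature_count


def species_of_offset(profile: EndProfile, ofs: int, ref: RdnaReference) -> Species:
    lo, hi = ref.a1_window
    if ofs < 0:
        return Species.UPSTREAM_OF_D
    if ofs == 0:
        return Species.MATURE_18S
    if lo <= ofs <= hi:
        return Species.PRE18S_A1
    if ofs == profile.a2_offset:
        return Species.PRE18S_A2
    return Species.PRE18S_OTHER


def _offsets_for_species(profile: EndProfile, ref: RdnaReference, species_set) -> set:
    offsets = set()
    for ofs in set(profile.end_counts) | {k[0] for k in profile.tail_counts}:
        if species_of_offset(profile, ofs, ref) in species_set:
            offsets.add(ofs)
    return offsets


def tailed_fraction(
    profile: EndProfile,
    ref: RdnaReference,
    species_set: Iterable[Species] = (Species.PRE18S_A1, Species.PRE18S_A2),
    min_tail_len: int = 1,
) -> float:
    """Percent of reads in ``species_set`` carrying a tail of at least
    ``min_tail_len`` nontemplated nucleotides, relative to mature 18S."""
    if profile.mature_count == 0:
        return math.nan
    wanted = _offsets_for_species(profile, ref, set(species_set))
    n = sum(
        c
        for (ofs, tlen, _comp), c in profile.tail_counts.items()
        if ofs in wanted and tlen >= min_tail_len
    )
    return 100.0 * n / profile.mature_count


def tail_composition(
    profile: EndProfile,
    calls: Iterable[JunctionCall],
    ref: RdnaReference,
    species_set: Iterable[Species] = (Species.PRE18S_A1, Species.PRE18S_A2),
) -> Dict[str, float]:
    """Per-nucleotide fractions of tail bases (A/U/G/C) over all tails of
    the selected species; fractions sum to 1, NaN when no tailed read."""
    species_set = set(species_set)
    counts = {"A": 0, "U": 0, "G": 0, "C": 0}
    for call in calls:
        if call.status is not Status.RESOLVED or not call.tail_seq:
            continue
        if classify_species(call, ref) not in species_set:
            continue
        for base in call.tail_seq:
            counts["U" if base == "T" else base] = counts.get(
                "U" if base == "T" else base, 0
            ) + 1
    total = sum(counts.values())
    if total == 0:
        return {b: math.nan for b in counts}
    return {b: c / total for b, c in counts.items()}


def tail_bubble_table(profile: EndProfile) -> pd.DataFrame:
    """Bubble-plot table: one row per (offset, tail length) with counts
    normalized to mature 18S."""
    rows = []
    if profile.mature_count > 0:
        agg: Dict[Tuple[int, int], int] = {}
        for (ofs, tlen, _comp), c in profile.tail_counts.items():
            agg[(ofs, tlen)] = agg.get((ofs, tlen), 0) + c
        for (ofs, tlen), c in sorted(agg.items()):
            rows.append(
                {
                    "offset_from_D": ofs,
                    "tail_len": tlen,
                    "normalized_count": c / profile.mature_count,
                }
            )
    return pd.DataFrame(rows, columns=["offset_from_D", "tail_len", "normalized_count"])


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    flag: str = ""


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "mann_whitney",
) -> GroupComparison:
    """Two-group comparison with the method recorded in the result.

    ``mann_whitney`` uses the exact null distribution for small samples
    without ties; ``welch_t`` and ``student_t`` are unpaired t tests.
    P values are two-sided.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(
            math.nan, math.nan, method, len(a), len(b), flag="insufficient_group_size"
        )
    if method == "mann_whitney":
        # small samples: exact permutation null (deterministic, tie-safe);
        # larger samples: scipy's default exact/asymptotic choice
        if len(a) + len(b) <= 14:
            mw_method = stats.PermutationMethod()
        else:
            mw_method = "auto"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(stat):  # zero variance in both groups
            stat, p = 0.0, 1.0
    elif method == "student_t":
        res = stats.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(stat):
            stat, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(stat, min(p, 1.0), method, len(a), len(b))


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """BH-adjusted p values (optional; per-position tests are reported
    unadjusted by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.clip(ranked, 0, 1)
    return out.tolist()


def profile_table(profile: EndProfile) -> pd.DataFrame:
    """End-profile table: offset, count, relative % versus mature 18S."""
    rel = normalize_to_mature(profile)
    rows = [
        {
            "library_id": profile.library_id,
            "genotype": profile.genotype,
            "fraction": profile.fraction,
            "replicate": profile.replicate,
            "offset_from_D": ofs,
            "count": c,
            "relative_percent": 100.0 * rel[ofs] if not math.isnan(rel[ofs]) else math.nan,
        }
        for ofs, c in profile.end_counts.items()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "library_id", "genotype", "fraction", "replicate",
            "offset_from_D", "count", "relative_percent",
        ],
    )
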