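"""The 45S rDNA reference model.

A single rDNA unit carries, in order, the nontranscribed spacer (NTS), the
5' external transcribed spacer, the 18S rRNA, ITS1, 5.8S, ITS2, 25S and the
3' external transcribed spacer.  Processing-site coordinates anchor all
downstream analyses:

* ``P2`` — the 5' end of mature 18S rRNA (the molecule-level filter used by
  the END-seq pipeline);
* ``D`` — the last templated nucleotide of mature 18S; every 3'-end call is
  reported as a signed offset from D;
* the ``A1`` window — a cluster of processing hotspots a configurable 8-13 nt
  downstream of D;
* ``A2``/``A3`` — endonucleolytic cleavage sites in ITS1.

Internally every coordinate is 0-based half-open; report files are 1-based
inclusive, the usual genome-browser convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import yaml

from .io import read_single_fasta

logger = logging.getLogger(__name__)

REGION_ORDER = ("NTS", "5'ETS", "18S", "ITS1", "5.8S", "ITS2", "25S", "3'ETS")
SITE_NAMES = ("P", "P'", "P2", "D", "A2", "A3")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceValidationError(ValueError):
    """Raised when the reference annotation violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on the reference."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ReferenceValidationError(
                f"invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ReferenceValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class RdnaReference:
    """One 45S rDNA unit with named processing sites and subregions."""

    name: str
    sequence: str
    subregions: Dict[str, GenomicInterval]
    sites: Dict[str, int]
    a1_window: Tuple[int, int] = (8, 13)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ReferenceValidationError("empty reference sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ReferenceValidationError(
                f"non-nucleotide characters in reference: {sorted(bad)}"
            )
        for region in REGION_ORDER:
            if region not in self.subregions:
                raise ReferenceValidationError(f"missing subregion {region!r}")
        for site in SITE_NAMES:
            if site not in self.sites:
                raise ReferenceValidationError(f"missing site {site!r}")
        prev_end = 0
        prev_name = None
        for region in REGION_ORDER:
            iv = self.subregions[region]
            if iv.end > n:
                raise ReferenceValidationError(
                    f"subregion {region!r} extends past the sequence end"
                )
            if iv.start < prev_end:
                raise ReferenceValidationError(
                    f"subregion {region!r} overlaps or precedes {prev_name!r}"
                )
            prev_end, prev_name = iv.end, region
        for site, pos in self.sites.items():
            if not (0 <= pos < n):
                raise ReferenceValidationError(f"site {site!r} outside the sequence")
        s18 = self.subregions["18S"]
        if self.sites["P2"] != s18.start:
            raise ReferenceValidationError(
                "site 'P2' must equal the 18S start (5' end of mature 18S)"
            )
        if self.sites["D"] != s18.end - 1:
            raise ReferenceValidationError(
                "site 'D' must be the last templated nucleotide of mature 18S"
            )
        d, a2, a3 = self.sites["D"], self.sites["A2"], self.sites["A3"]
        if not (d < a2 < a3):
            raise ReferenceValidationError("sites must be ordered D < A2 < A3")
        its1 = self.subregions["ITS1"]
        for site in ("A2", "A3"):
            if not (its1.start <= self.sites[site] < its1.end):
                raise ReferenceValidationError(f"site {site!r} must lie within ITS1")
        lo, hi = self.a1_window
        if not (0 < lo <= hi):
            raise ReferenceValidationError("a1_window offsets must satisfy 0 < lo <= hi")
        if d + hi >= a2:
            raise ReferenceValidationError(
                "a1_window must lie strictly between D and A2"
            )
        ets5 = self.subregions["5'ETS"]
        for site in ("P", "P'"):
            if not (ets5.start <= self.sites[site] < s18.start):
                raise ReferenceValidationError(
                    f"site {site!r} must lie in the 5' ETS, upstream of 18S"
                )

    # -- coordinate arithmetic ----------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    def offset_from_d(self, pos: int) -> int:
        """Signed offset of ``pos`` from the D site; 0 is the mature 18S 3' end."""
        if not (0 <= pos < len(self.sequence)):
            raise ValueError(f"position {pos} outside reference [0, {len(self)})")
        return pos - self.sites["D"]

    @property
    def a1_interval(self) -> GenomicInterval:
        """Positions D+lo .. D+hi inclusive, as a half-open interval."""
        d = self.sites["D"]
        lo, hi = self.a1_window
        return GenomicInterval(d + lo, d + hi + 1)

    @property
    def a2_offset(self) -> int:
        return self.sites["A2"] - self.sites["D"]

    def layout_summary(self) -> str:
        parts = [
            f"{r}:{self.subregions[r].start + 1}-{self.subregions[r].end}"
            for r in REGION_ORDER
        ]
        return f"{self.name} ({len(self)} nt) " + " ".join(parts)


def _as_interval(name: str, value) -> GenomicInterval:
    """Convert a 1-based inclusive ``[start, end]`` pair from the config file."""
    try:
        start, end = int(value[0]), int(value[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ReferenceValidationError(
            f"subregion {name!r}: expected [start, end], got {value!r}"
        ) from exc
    return GenomicInterval(start - 1, end)


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> RdnaReference:
    """Load and validate the rDNA reference from FASTA + YAML annotation.

    The annotation file uses 1-based inclusive coordinates under
    ``subregions:`` (``name: [start, end]``) and ``sites:`` (``name: pos``),
    plus an optional ``a1_window: [lo, hi]`` pair of offsets from D.
    """
    name, sequence = read_single_fasta(fasta_path)
    with open(annotation_path) as handle:
        ann = yaml.safe_load(handle)
    if not isinstance(ann, Mapping):
        raise ReferenceValidationError(f"{annotation_path}: not a mapping")
    for key in ("subregions", "sites"):
        if key not in ann:
            raise ReferenceValidationError(f"{annotation_path}: missing key {key!r}")
    subregions = {
        str(k): _as_interval(str(k), v) for k, v in ann["subregions"].items()
    }
    sites = {str(k): int(v) - 1 for k, v in ann["sites"].items()}
    a1_window = tuple(ann.get("a1_window", (8, 13)))
    ref = RdnaReference(
        name=name,
        sequence=sequence,
        subregions=subregions,
        sites=sites,
        a1_window=a1_window,  # type: ignore[arg-type]
    )
    logger.info("loaded reference %s", ref.layout_summary())
    return ref


def write_annotation(path: str | Path, ref: RdnaReference) -> None:
    """Write the annotation back out in the 1-based YAML dialect."""
    doc = {
        "subregions": {
            r: [ref.subregions[r].start + 1, ref.subregions[r].end]
            for r in REGION_ORDER
        },
        "sites": {s: ref.sites[s] + 1 for s in SITE_NAMES},
        "a1_window": list(ref.a1_window),
    }
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)
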