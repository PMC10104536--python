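"""Ribosome-profiling P-site assignment and the ATG stalling index.

Footprint alignments live in transcript coordinates (a SAM file aligned to
a transcriptome works directly; a plain TSV of 5'-end positions works
too).  For each footprint length an offset from the 5' end to the P site
is estimated by maximizing the count landing exactly on annotated start
codons; P-site tracks then feed metagene profiles, 3-nt periodicity and
feature QC, and the per-gene ATG stalling index — the fraction of ORF
P-site counts sitting on the start codon.  Mutant/wild-type per-gene
fold changes of the index are summarized by their median and a one-sided
t test on log2 fold change.

Footprint collections are plain DataFrames with columns
``transcript_id``, ``five_prime`` (0-based) and ``length`` so that
million-footprint libraries stay cheap; :class:`Footprint` records are
accepted everywhere and converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_OFFSET = 12
FOOTPRINT_COLUMNS = ["transcript_id", "five_prime", "length"]


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript with its CDS in transcript coordinates."""

    gene_id: str
    transcript_id: str
    length: int
    cds_start: int  # first nucleotide of the ATG, 0-based
    cds_end: int    # exclusive; includes the stop codon

    def __post_init__(self):
        cds_len = self.cds_end - self.cds_start
        if cds_len <= 0 or cds_len % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {cds_len} not a positive multiple of 3"
            )
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise ValueError(f"{self.transcript_id}: CDS outside transcript")

    @property
    def stop_codon_start(self) -> int:
        return self.cds_end - 3


@dataclass(frozen=True)
class Footprint:
    transcript_id: str
    five_prime: int  # 0-based transcript coordinate of the footprint 5' end
    length: int


def footprints_to_frame(footprints) -> pd.DataFrame:
    """Normalize a footprint collection to the canonical DataFrame form."""
    if isinstance(footprints, pd.DataFrame):
        return footprints[FOOTPRINT_COLUMNS]
    return pd.DataFrame(
        {
            "transcript_id": pd.Categorical([f.transcript_id for f in footprints]),
            "five_prime": np.fromiter((f.five_prime for f in footprints), dtype=np.int64,
                                      count=len(footprints)),
            "length": np.fromiter((f.length for f in footprints), dtype=np.int64,
                                  count=len(footprints)),
        }
    )


def _tx_column(transcripts: Mapping[str, TranscriptModel], attr: str) -> pd.Series:
    return pd.Series({tid: getattr(t, attr) for tid, t in transcripts.items()})


def read_transcripts_tsv(path: str | Path) -> Dict[str, TranscriptModel]:
    """Load transcript models from a TSV with 1-based inclusive CDS columns
    (gene_id, transcript_id, length, cds_start, cds_end)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        t = TranscriptModel(
            gene_id=str(row.gene_id),
            transcript_id=str(row.transcript_id),
            length=int(row.length),
            cds_start=int(row.cds_start) - 1,
            cds_end=int(row.cds_end),
        )
        out[t.transcript_id] = t
    return out


def read_footprints_tsv(path: str | Path) -> pd.DataFrame:
    """Load footprints from a TSV (transcript_id, five_prime 1-based, length)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"transcript_id": "category", "five_prime": np.int64, "length": np.int64},
    )
    df["five_prime"] = df["five_prime"] - 1
    return df[FOOTPRINT_COLUMNS]


def read_footprints_sam(path: str | Path) -> pd.DataFrame:
    """Load footprints from a transcriptome SAM/BAM (forward-strand reads)."""
    import pysam

    tids, fives, lengths = [], [], []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_reverse:
                continue
            tids.append(rec.reference_name)
            fives.append(rec.reference_start)
            lengths.append(rec.query_length)
    return pd.DataFrame(
        {
            "transcript_id": pd.Categorical(tids),
            "five_prime": np.asarray(fives, dtype=np.int64),
            "length": np.asarray(lengths, dtype=np.int64),
        }
    )


def length_distribution(footprints) -> Tuple[Dict[int, int], List[int]]:
    """Histogram of footprint lengths and its mode(s), smaller length first."""
    df = footprints_to_frame(footprints)
    if df.empty:
        return {}, []
    counts = df["length"].value_counts()
    hist = {int(l): int(c) for l, c in counts.sort_index().items()}
    peak = counts.max()
    modes = sorted(int(l) for l, c in counts.items() if c == peak)
    return hist, modes


def estimate_offsets(
    footprints,
    transcripts: Mapping[str, TranscriptModel],
    candidate_range: Iterable[int] = range(10, 16),
    min_per_class: int = 100,
) -> Tuple[Dict[int, int], Dict[int, str]]:
    """Estimate the 5'-end-to-P-site offset per footprint length.

    For each length class the offset maximizing the number of footprints
    whose shifted 5' end lands exactly on an annotated start codon wins;
    ties break toward the canonical offset 12, and sparse classes
    (< ``min_per_class`` footprints) fall back to 12 with a flag.
    """
    candidates = list(candidate_range)
    df = footprints_to_frame(footprints)
    cds_start = df["transcript_id"].map(_tx_column(transcripts, "cds_start"))
    delta = df["five_prime"].to_numpy() - cds_start.to_numpy(dtype=float)
    lengths_arr = df["length"].to_numpy()
    offsets: Dict[int, int] = {}
    flags: Dict[int, str] = {}
    for length in sorted(np.unique(lengths_arr)):
        sel = delta[lengths_arr == length]
        if len(sel) < min_per_class:
            offsets[int(length)] = DEFAULT_OFFSET
            flags[int(length)] = "sparse_default"
            continue
        scores = {o: int(np.sum(sel == -o)) for o in candidates}
        best = max(scores.values())
        winners = [o for o in candidates if scores[o] == best]
        offsets[int(length)] = min(winners, key=lambda o: (abs(o - DEFAULT_OFFSET), o))
        if len(winners) > 1:
            flags[int(length)] = "tie_default"
    return offsets, flags


@dataclass
class PsiteTrack:
    """Sparse per-(transcript, position) P-site counts for one library."""

    library_id: str
    frame: pd.DataFrame  # columns transcript_id, pos, count
    offsets: Dict[int, int] = field(default_factory=dict)
    dropped: int = 0

    @property
    def total(self) -> float:
        return float(self.frame["count"].sum())

    def count_at(self, transcript_id: str, pos: int) -> float:
        sel = self.frame[
            (self.frame["transcript_id"] == transcript_id) & (self.frame["pos"] == pos)
        ]
        return float(sel["count"].sum())


def assign_psites(
    footprints,
    offsets: Mapping[int, int],
    transcripts: Mapping[str, TranscriptModel],
    library_id: str = "",
) -> PsiteTrack:
    """P-site position = footprint 5' end + offset[length].

    Footprints of unmodeled length, with an offset not smaller than their
    length, or whose P site falls outside the transcript are dropped and
    counted.
    """
    df = footprints_to_frame(footprints)
    n_in = len(df)
    off = df["length"].map(dict(offsets)).astype(float)
    keep = off.notna() & (off < df["length"])
    pos = df["five_prime"] + off.fillna(0).astype(np.int64)
    tlen = df["transcript_id"].map(_tx_column(transcripts, "length")).astype(float)
    keep &= tlen.notna() & (pos >= 0) & (pos < tlen.fillna(0))
    kept = pd.DataFrame(
        {"transcript_id": df["transcript_id"][keep], "pos": pos[keep]}
    )
    grouped = (
        kept.groupby(["transcript_id", "pos"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["transcript_id", "pos"], ignore_index=True)
    )
    grouped["count"] = grouped["count"].astype(float)
    return PsiteTrack(
        library_id=library_id,
        frame=grouped,
        offsets=dict(offsets),
        dropped=int(n_in - keep.sum()),
    )


def _annotated(track: PsiteTrack, transcripts: Mapping[str, TranscriptModel]) -> pd.DataFrame:
    df = track.frame.copy()
    df["cds_start"] = df["transcript_id"].map(_tx_column(transcripts, "cds_start")).astype(float)
    df["cds_end"] = df["transcript_id"].map(_tx_column(transcripts, "cds_end")).astype(float)
    return df[df["cds_start"].notna()]


def metagene(
    track: PsiteTrack,
    transcripts: Mapping[str, TranscriptModel],
    half_window: int = 20,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Start- and stop-anchored metagene profiles over a 41-nt window.

    Each transcript's window counts are normalized by their own sum, then
    averaged over transcripts with nonzero windows; returns
    ``(offsets, start_profile, stop_profile)``.
    """
    w = 2 * half_window + 1
    df = _annotated(track, transcripts)
    profiles = []
    for anchor in (df["cds_start"], df["cds_end"] - 3):
        rel = (df["pos"] - anchor).to_numpy(dtype=np.int64)
        sel = np.abs(rel) <= half_window
        if not sel.any():
            profiles.append(np.zeros(w))
            continue
        tid_codes, _ = pd.factorize(df["transcript_id"].to_numpy()[sel])
        counts = df["count"].to_numpy()[sel]
        per_tid = np.bincount(tid_codes, weights=counts)
        norm = counts / per_tid[tid_codes]
        profile = np.bincount(rel[sel] + half_window, weights=norm, minlength=w)
        profiles.append(profile / len(per_tid))
    offsets = np.arange(-half_window, half_window + 1)
    return offsets, profiles[0], profiles[1]


def frame_fractions(
    track: PsiteTrack, transcripts: Mapping[str, TranscriptModel]
) -> np.ndarray:
    """Fractions of CDS P-site counts by reading frame (pos - start) mod 3."""
    df = _annotated(track, transcripts)
    in_cds = (df["pos"] >= df["cds_start"]) & (df["pos"] < df["cds_end"])
    rel = (df["pos"] - df["cds_start"])[in_cds].to_numpy(dtype=np.int64) % 3
    counts = df["count"][in_cds].to_numpy()
    frames = np.bincount(rel, weights=counts, minlength=3)
    total = frames.sum()
    return frames / total if total > 0 else frames


def feature_fractions(
    track: PsiteTrack, transcripts: Mapping[str, TranscriptModel]
) -> Dict[str, float]:
    """Fractions of P-site counts in the 5' UTR, CDS and 3' UTR."""
    df = _annotated(track, transcripts)
    total = df["count"].sum()
    if total == 0:
        return {"5'UTR": math.nan, "CDS": math.nan, "3'UTR": math.nan}
    utr5 = df["count"][df["pos"] < df["cds_start"]].sum()
    cds = df["count"][(df["pos"] >= df["cds_start"]) & (df["pos"] < df["cds_end"])].sum()
    return {
        "5'UTR": float(utr5 / total),
        "CDS": float(cds / total),
        "3'UTR": float((total - utr5 - cds) / total),
    }


def stalling_indexes(
    track: PsiteTrack,
    transcripts: Mapping[str, TranscriptModel],
    min_counts: int = 10,
    codon_level: bool = True,
) -> Dict[str, Optional[float]]:
    """Per-gene ATG stalling index for one library (keyed by gene_id).

    The index is the ratio of P-site counts on the ATG start codon (all
    three codon nucleotides by default, the first nucleotide only with
    ``codon_level=False``) to all P-site counts in the ORF; ``None`` when
    the ORF total is below ``min_counts``.
    """
    df = _annotated(track, transcripts)
    in_orf = (df["pos"] >= df["cds_start"]) & (df["pos"] < df["cds_end"])
    df = df[in_orf]
    atg_span = 3 if codon_level else 1
    on_atg = df["pos"] < df["cds_start"] + atg_span
    orf_totals = df.groupby("transcript_id", observed=True)["count"].sum()
    atg_totals = df[on_atg].groupby("transcript_id", observed=True)["count"].sum()
    out: Dict[str, Optional[float]] = {}
    for tid in sorted(transcripts):
        t = transcripts[tid]
        total = float(orf_totals.get(tid, 0.0))
        if total < min_counts:
            out[t.gene_id] = None
        else:
            out[t.gene_id] = float(atg_totals.get(tid, 0.0)) / total
    return out


def atg_stalling_index(
    track: PsiteTrack,
    transcript: TranscriptModel,
    min_counts: int = 10,
    codon_level: bool = True,
) -> Optional[float]:
    """Start-codon stalling index of a single gene (see stalling_indexes)."""
    one = {transcript.transcript_id: transcript}
    return stalling_indexes(track, one, min_counts, codon_level)[transcript.gene_id]


def average_replicates(
    replicate_indexes: Sequence[Mapping[str, Optional[float]]],
) -> Dict[str, Optional[float]]:
    """Mean per-gene index over replicates; a gene must be defined in every
    replicate to stay defined."""
    genes = set()
    for rep in replicate_indexes:
        genes |= set(rep)
    out: Dict[str, Optional[float]] = {}
    for g in sorted(genes):
        vals = [rep.get(g) for rep in replicate_indexes]
        out[g] = None if any(v is None for v in vals) else float(np.mean(vals))
    return out


@dataclass
class StallTable:
    table: pd.DataFrame  # gene_id, index_mut, index_wt, fc, log2_fc
    median_fc: float
    statistic: float
    p_value: float
    method: str
    n_genes: int
    n_excluded: int
    flags: List[str] = field(default_factory=list)


def stalling_fold_change(
    mut_indexes: Mapping[str, Optional[float]],
    wt_indexes: Mapping[str, Optional[float]],
    alternative: str = "greater",
    two_sample: bool = False,
) -> StallTable:
    """Per-gene fold change of the ATG stalling index, mutant over WT.

    Genes with an undefined index in either genotype, or a WT index of 0
    (which would give an infinite ratio), are excluded and counted.  The
    summary is the median fold change plus a one-sided, one-sample t test
    of log2 fold change against 0 (a two-sample t on log2 indexes is
    available via ``two_sample``; genes with a zero mutant index are then
    also excluded to keep the logs finite).
    """
    rows = []
    excluded = 0
    for gene in sorted(set(mut_indexes) & set(wt_indexes)):
        im, iw = mut_indexes[gene], wt_indexes[gene]
        if im is None or iw is None or iw == 0 or (two_sample and im == 0):
            excluded += 1
            continue
        fc = im / iw
        rows.append(
            {"gene_id": gene, "index_mut": im, "index_wt": iw,
             "fc": fc, "log2_fc": math.log2(fc) if fc > 0 else -math.inf}
        )
    table = pd.DataFrame(rows, columns=["gene_id", "index_mut", "index_wt", "fc", "log2_fc"])
    flags = []
    if len(table) < 10:
        flags.append("low_power")
    if len(table) == 0:
        return StallTable(table, math.nan, math.nan, math.nan,
                          "t_one_sample_log2fc", 0, excluded, flags)
    median_fc = float(table["fc"].median())
    finite = table[np.isfinite(table["log2_fc"])]
    log2fc = finite["log2_fc"].to_numpy()
    if two_sample:
        method = "t_two_sample_log2index"
        a = np.log2(finite["index_mut"].to_numpy())
        b = np.log2(finite["index_wt"].to_numpy())
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        method = "t_one_sample_log2fc"
        if len(log2fc) == 0 or np.allclose(log2fc, log2fc[0]):
            stat, p = math.nan, math.nan
            flags.append("degenerate_variance")
        else:
            res = stats.ttest_1samp(log2fc, 0.0, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
    return StallTable(
        table=table,
        median_fc=median_fc,
        statistic=stat,
        p_value=p,
        method=method,
        n_genes=len(table),
        n_excluded=excluded,
        flags=flags,
    )
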