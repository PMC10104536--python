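"""Seeded simulators with ground-truth tables for every pipeline stage.

Each generator derives its randomness from one top-level seed through a
named substream, so adding a new generator never perturbs existing
outputs, and each writes a truth table sufficient to score the matching
pipeline without re-deriving ground truth.

Design notes
------------
* The synthetic rDNA unit uses realistic region lengths (18S 1.8 kb,
  ITS1 0.3 kb, 25S 3.4 kb ...).  The ITS1 segment that can host simulated
  3' ends — and the base immediately upstream of P2 — are drawn from
  {C, G} only, so that the A/U-dominated nontemplated tails the tail model
  emits can never coincide with the templated continuation.  This keeps
  every sampled junction identifiable; plant ITS1 is genuinely GC-rich,
  but the hard constraint is a deliberate idealization.
* For tail models that do allow such coincidences (e.g. uniform ACGT
  tails), the truth table is canonicalized by maximal templated extension,
  i.e. it records the anatomy of the read, which is the only thing any
  caller can recover.
* Substitution-only error model; indels are outside the default model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reference import REGION_ORDER, GenomicInterval, RdnaReference, revcomp, write_annotation
from .ribo import TranscriptModel
from .io import write_fasta, write_fastq

_BASES = np.array(list("ACGT"))

DEFAULT_REGION_LENGTHS = {
    "NTS": 500,
    "5'ETS": 1000,
    "18S": 1800,
    "ITS1": 300,
    "5.8S": 160,
    "ITS2": 220,
    "25S": 3400,
    "3'ETS": 300,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named substream of a top-level seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# reference


def make_reference(
    seed: int,
    region_lengths: Optional[Mapping[str, int]] = None,
    a2_offset_from_d: int = 90,
    a3_offset_from_d: int = 250,
    name: str = "rDNA_45S_synthetic",
) -> RdnaReference:
    """Random rDNA unit satisfying every reference invariant.

    ``a2_offset_from_d``/``a3_offset_from_d`` place the ITS1 cleavage
    sites downstream of D; both must fall inside ITS1.
    """
    lengths = dict(DEFAULT_REGION_LENGTHS)
    if region_lengths:
        lengths.update(region_lengths)
    for region, n in lengths.items():
        if n <= 0:
            raise ValueError(f"region {region!r} has non-positive length")
    if lengths["18S"] < 200:
        raise ValueError("18S must be at least 200 nt")
    if not (0 < a2_offset_from_d < a3_offset_from_d <= lengths["ITS1"]):
        raise ValueError("A2/A3 offsets must fit inside ITS1")

    rng = substream(seed, "reference")
    total = sum(lengths[r] for r in REGION_ORDER)
    seq = rng.choice(_BASES, size=total)

    subregions = {}
    pos = 0
    for region in REGION_ORDER:
        subregions[region] = GenomicInterval(pos, pos + lengths[region])
        pos += lengths[region]
    d = subregions["18S"].end - 1
    p2 = subregions["18S"].start
    a2 = d + a2_offset_from_d
    # 3' ends may fall anywhere in (D, A2]; keep the continuation bases and
    # the base 5' of P2 free of A/T so A/U tails are always nontemplated
    gc = np.array(list("CG"))
    seq[d + 1 : a2 + 2] = rng.choice(gc, size=a2 + 1 - d)
    seq[p2 - 1] = rng.choice(gc)

    sites = {
        "P": subregions["5'ETS"].start,
        "P'": subregions["5'ETS"].start + lengths["5'ETS"] // 2,
        "P2": p2,
        "D": d,
        "A2": a2,
        "A3": d + a3_offset_from_d,
    }
    return RdnaReference(
        name=name,
        sequence="".join(seq),
        subregions=subregions,
        sites=sites,
    )


def write_reference(ref: RdnaReference, fasta_path, annotation_path) -> None:
    write_fasta(fasta_path, ref.name, ref.sequence)
    write_annotation(annotation_path, ref)


# ---------------------------------------------------------------------------
# END-seq


def endseq_end_distribution(ref: RdnaReference, pre18s_ratio: float = 0.0146) -> Dict[int, float]:
    """End distribution with a given precursor:mature ratio.

    Precursor mass is split half across the A1 hotspot window and half at
    A2, mirroring the two dominant precursor species.
    """
    p_pre = pre18s_ratio / (1.0 + pre18s_ratio)
    lo, hi = ref.a1_window
    a1_offsets = list(range(lo, hi + 1))
    dist = {0: 1.0 - p_pre}
    for o in a1_offsets:
        dist[o] = 0.5 * p_pre / len(a1_offsets)
    dist[ref.a2_offset] = dist.get(ref.a2_offset, 0.0) + 0.5 * p_pre
    return dist


@dataclass
class EndseqSimConfig:
    """Study conditions for the END-seq read simulator.

    The defaults mirror a wild-type library: 150-nt single-end reads, a
    precursor:mature ratio of 1.46%, nontemplated tails on 30% of
    precursor molecules and 5% of mature molecules with A:U = 9:1
    composition, and a 0.1% substitution error rate.
    """

    n_reads: int = 50_000
    read_len: int = 150
    end_distribution: Optional[Dict[int, float]] = None  # offset from D -> prob
    pre18s_ratio: float = 0.0146
    tail_prob_pre: float = 0.3
    tail_prob_mature: float = 0.05
    tail_len_probs: Tuple[float, ...] = (0.5, 0.25, 0.125, 0.125)  # lengths 1..4
    tail_composition: Tuple[float, float, float, float] = (0.9, 0.0, 0.0, 0.1)  # A,C,G,T(U)
    error_rate: float = 0.001
    min_arm: int = 20

    def __post_init__(self):
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        if abs(sum(self.tail_composition) - 1.0) > 1e-9:
            raise ValueError("tail composition weights must sum to 1")
        if abs(sum(self.tail_len_probs) - 1.0) > 1e-9:
            raise ValueError("tail length probabilities must sum to 1")


def _canonicalize_truth(ref: RdnaReference, five: int, three: int, tail: str):
    """Record the maximal-templated-extension anatomy of a sampled read.

    A tail base equal to the adjacent templated base is indistinguishable
    from template; the truth table stores the canonical split (5'-arm
    absorption first, mirroring longest-suffix preference).
    """
    seq = ref.sequence
    while tail and five > 0 and tail[-1] == seq[five - 1]:
        five -= 1
        tail = tail[:-1]
    while tail and three + 1 < len(seq) and tail[0] == seq[three + 1]:
        three += 1
        tail = tail[1:]
    return five, three, tail


def sim_endseq(
    ref: RdnaReference,
    config: EndseqSimConfig,
    seed: int,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Simulate circularized END-seq reads with a ground-truth table.

    Returns ``(records, truth)`` where records are ``(read_id, sequence)``
    and the truth table holds the canonical 5' end, templated 3' end,
    tail, and species offset of every read (0-based positions).
    """
    rng = substream(seed, "endseq")
    dist = config.end_distribution or endseq_end_distribution(ref, config.pre18s_ratio)
    offsets = np.array(sorted(dist))
    probs = np.array([dist[o] for o in offsets], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("end distribution probabilities must sum to 1")
    d, p2 = ref.sites["D"], ref.sites["P2"]
    win_hi = ref.sites["A3"]
    if offsets.max() + d > win_hi or offsets.min() + d < 0:
        raise ValueError("end distribution mass outside the reference window")

    seq = ref.sequence
    n = config.n_reads
    ends = offsets[rng.choice(len(offsets), size=n, p=probs)]
    tail_lens = np.zeros(n, dtype=int)
    is_pre = ends != 0
    tp = np.where(is_pre, config.tail_prob_pre, config.tail_prob_mature)
    tailed = rng.random(n) < tp
    lens = rng.choice(np.arange(1, len(config.tail_len_probs) + 1), size=n, p=config.tail_len_probs)
    tail_lens[tailed] = lens[tailed]

    records = []
    truth_rows = []
    comp = np.asarray(config.tail_composition, dtype=float)
    for i in range(n):
        e = d + int(ends[i])
        tl = int(tail_lens[i])
        tail = "".join(rng.choice(_BASES, size=tl, p=comp)) if tl else ""
        # junction placed uniformly subject to both arms >= min_arm
        lo3 = config.min_arm
        hi3 = config.read_len - tl - config.min_arm
        if hi3 < lo3:
            raise ValueError("read too short for the configured arms and tail")
        l3 = int(rng.integers(lo3, hi3 + 1))
        l5 = config.read_len - tl - l3
        read = seq[e - l3 + 1 : e + 1] + tail + seq[p2 : p2 + l5]
        if config.error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").astype("U1")
            hit = np.flatnonzero(rng.random(len(arr)) < config.error_rate)
            for j in hit:
                choices = [b for b in "ACGT" if b != arr[j]]
                arr[j] = choices[int(rng.integers(3))]
            read = "".join(arr)
        t5, t3, ttail = _canonicalize_truth(ref, p2, e, tail)
        records.append((f"read{i:07d}", read))
        truth_rows.append(
            {
                "read_id": f"read{i:07d}",
                "true_five_prime": t5,
                "true_three_prime": t3,
                "true_tail": ttail,
                "true_offset": t3 - d,
                "sampled_offset": int(ends[i]),
                "sampled_tail_len": tl,
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# small RNA


def default_srna_abundances(ref: RdnaReference, genotype: str = "wt") -> Dict[Tuple[str, str, int], float]:
    """Per-(region, strand, length) expected read counts per million.

    Wild type carries only a low sense background; the mutant adds strong
    21/22-nt antisense signal over 18S and 25S and both strands of the
    18S-ITS1 linker, the hallmark risiRNA pattern.
    """
    base: Dict[Tuple[str, str, int], float] = {}
    for region in REGION_ORDER:
        for length in (21, 22, 24):
            base[(region, "+", length)] = 20.0
            base[(region, "-", length)] = 20.0
    if genotype != "wt":
        for length in (21, 22):
            base[("18S", "-", length)] = 200.0
            base[("25S", "-", length)] = 120.0
            base[("18S-ITS1", "+", length)] = 80.0
            base[("18S-ITS1", "-", length)] = 80.0
    return base


def sim_srna(
    ref: RdnaReference,
    abundances: Mapping[Tuple[str, str, int], float],
    depth: int,
    seed: int,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Sample a small-RNA library from planted per-cell abundances.

    ``abundances`` maps (region, strand, length) to sampling weight; the
    special region ``18S-ITS1`` places reads straddling the 18S/ITS1
    boundary.  Reads are positioned uniformly inside their region.
    """
    rng = substream(seed, "srna")
    cells = sorted(abundances)
    for region, strand, length in cells:
        if region != "18S-ITS1" and region not in ref.subregions:
            raise ValueError(f"abundance for undefined region {region!r}")
        if strand not in "+-":
            raise ValueError(f"invalid strand {strand!r}")
    weights = np.array([abundances[c] for c in cells], dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(depth, weights)
    boundary = ref.subregions["18S"].end

    records = []
    truth_rows = []
    idx = 0
    for cell, c in zip(cells, counts):
        region, strand, length = cell
        if region == "18S-ITS1":
            lo = boundary - length + 1
            hi = boundary - 1
        else:
            iv = ref.subregions[region]
            lo, hi = iv.start, iv.end - length
        if hi < lo:
            raise ValueError(f"region {region!r} shorter than read length {length}")
        starts = rng.integers(lo, hi + 1, size=c)
        for s in starts:
            frag = ref.sequence[s : s + length]
            records.append((f"srna{idx:07d}", frag if strand == "+" else revcomp(frag)))
            idx += 1
        truth_rows.append(
            {"region": region, "strand": strand, "length": length, "true_count": int(c)}
        )
    # deterministic shuffle so cells are not block-ordered in the FASTQ
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ribosome footprints


@dataclass
class RiboSimConfig:
    """Study conditions for the footprint simulator.

    Defaults: 2,000 genes, ORFs of 100-400 codons, footprints peaking at
    28 nt, per-length P-site offsets around 12, 90% of P-sites in frame 0,
    and a mean depth of 60 P-sites per gene.
    """

    n_genes: int = 2000
    orf_codons: Tuple[int, int] = (100, 400)
    utr5: int = 60
    utr3: int = 60
    length_probs: Dict[int, float] = field(
        default_factory=lambda: {26: 0.05, 27: 0.20, 28: 0.50, 29: 0.15, 30: 0.10}
    )
    offsets: Dict[int, int] = field(
        default_factory=lambda: {26: 11, 27: 12, 28: 12, 29: 13, 30: 13}
    )
    frame_bias: float = 0.9
    stall_median: float = 1.0
    stall_sigma: float = 0.0  # lognormal spread of per-gene amplification
    depth_per_gene: float = 1000.0

    def __post_init__(self):
        if abs(sum(self.length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("length probabilities must sum to 1")
        if self.stall_median < 1.0:
            raise ValueError("stall amplification must be >= 1")
        for length, off in self.offsets.items():
            if not (0 <= off < length):
                raise ValueError(f"offset {off} not within footprint length {length}")
        missing = set(self.length_probs) - set(self.offsets)
        if missing:
            raise ValueError(f"no offset configured for lengths {sorted(missing)}")


def sim_transcriptome(config: RiboSimConfig, seed: int) -> Dict[str, TranscriptModel]:
    """Deterministic synthetic transcript models (no sequence needed)."""
    rng = substream(seed, "transcriptome")
    out = {}
    codons = rng.integers(config.orf_codons[0], config.orf_codons[1] + 1, size=config.n_genes)
    for i in range(config.n_genes):
        cds_len = int(codons[i]) * 3
        tid = f"T{i:05d}.1"
        out[tid] = TranscriptModel(
            gene_id=f"G{i:05d}",
            transcript_id=tid,
            length=config.utr5 + cds_len + config.utr3,
            cds_start=config.utr5,
            cds_end=config.utr5 + cds_len,
        )
    return out


def sim_ribo(
    config: RiboSimConfig,
    seed: int,
    transcripts: Optional[Dict[str, TranscriptModel]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, TranscriptModel]]:
    """Simulate a footprint library with per-gene start-codon stalling.

    P-site intensity is uniform over ORF codons except the start codon,
    whose weight is multiplied by the gene's stall amplification (lognormal
    across genes with median ``stall_median``).  Frame noise moves a P site
    within its codon, so the realized per-gene index in the truth table is
    exact.  Footprint 5' ends are placed at P-site minus the configured
    per-length offset.  Returns a footprint DataFrame (columns
    ``transcript_id``, ``five_prime``, ``length``), the truth table, and
    the transcript models.
    """
    rng = substream(seed, "ribo")
    if transcripts is None:
        transcripts = sim_transcriptome(config, seed)
    lengths = np.array(sorted(config.length_probs))
    lprobs = np.array([config.length_probs[l] for l in lengths])
    offset_of = np.zeros(int(lengths.max()) + 1, dtype=np.int64)
    for l in lengths:
        offset_of[l] = config.offsets[int(l)]

    tid_chunks, five_chunks, len_chunks = [], [], []
    truth_rows = []
    for tid in sorted(transcripts):
        t = transcripts[tid]
        n_codons = (t.cds_end - t.cds_start) // 3
        if config.stall_sigma > 0:
            amp = float(np.exp(np.log(config.stall_median)
                               + config.stall_sigma * rng.standard_normal()))
            amp = max(amp, 1.0)
        else:
            amp = config.stall_median
        n_fp = int(rng.poisson(config.depth_per_gene))
        w = np.ones(n_codons)
        w[0] = amp
        w /= w.sum()
        codons = rng.choice(n_codons, size=n_fp, p=w)
        noise = rng.random(n_fp)
        shift = np.zeros(n_fp, dtype=np.int64)
        off_frame = noise >= config.frame_bias
        shift[off_frame] = np.where(
            noise[off_frame] < (1 + config.frame_bias) / 2, 1, 2
        )
        fp_len = lengths[rng.choice(len(lengths), size=n_fp, p=lprobs)]
        pos = t.cds_start + 3 * codons + shift
        five = pos - offset_of[fp_len]
        ok = (five >= 0) & (five + fp_len <= t.length)
        tid_chunks.append(np.full(int(ok.sum()), tid, dtype=object))
        five_chunks.append(five[ok])
        len_chunks.append(fp_len[ok])
        truth_rows.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": tid,
                "amplification": amp,
                "n_psites": n_fp,
                "true_index": float(np.sum(codons == 0)) / n_fp if n_fp else np.nan,
            }
        )
    footprints = pd.DataFrame(
        {
            "transcript_id": pd.Categorical(np.concatenate(tid_chunks)),
            "five_prime": np.concatenate(five_chunks),
            "length": np.concatenate(len_chunks),
        }
    )
    return footprints, pd.DataFrame(truth_rows), transcripts


# ---------------------------------------------------------------------------
# writers


def write_endseq_dataset(outdir, ref, config, seed, prefix="endseq"):
    """Write FASTQ + truth TSV (and the reference pair) for an END-seq sim."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = sim_endseq(ref, config, seed)
    write_fastq(outdir / f"{prefix}.fastq", records)
    truth.to_csv(outdir / f"{prefix}.truth.tsv", sep="\t", index=False)
    return outdir / f"{prefix}.fastq", outdir / f"{prefix}.truth.tsv"


def write_srna_dataset(outdir, ref, abundances, depth, seed, prefix="srna"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = sim_srna(ref, abundances, depth, seed)
    write_fastq(outdir / f"{prefix}.fastq", records)
    truth.to_csv(outdir / f"{prefix}.truth.tsv", sep="\t", index=False)
    return outdir / f"{prefix}.fastq", outdir / f"{prefix}.truth.tsv"


def write_ribo_dataset(outdir, config, seed, prefix="ribo", transcripts=None):
    """Write footprints TSV + transcripts TSV + truth TSV for a ribo sim."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    footprints, truth, transcripts = sim_ribo(config, seed, transcripts)
    fp = footprints.assign(five_prime=footprints["five_prime"] + 1)
    fp.to_csv(outdir / f"{prefix}.footprints.tsv", sep="\t", index=False)
    tx = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in transcripts.values()],
            "transcript_id": [t.transcript_id for t in transcripts.values()],
            "length": [t.length for t in transcripts.values()],
            "cds_start": [t.cds_start + 1 for t in transcripts.values()],
            "cds_end": [t.cds_end for t in transcripts.values()],
        }
    ).sort_values("transcript_id")
    tx.to_csv(outdir / f"{prefix}.transcripts.tsv", sep="\t", index=False)
    truth.to_csv(outdir / f"{prefix}.truth.tsv", sep="\t", index=False)
    return (
        outdir / f"{prefix}.footprints.tsv",
        outdir / f"{prefix}.transcripts.tsv",
        outdir / f"{prefix}.truth.tsv",
    )
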