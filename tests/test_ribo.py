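"""P-site machinery: offsets, metagene, periodicity, stalling statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from preribo.ribo import (
    Footprint,
    PsiteTrack,
    TranscriptModel,
    assign_psites,
    atg_stalling_index,
    average_replicates,
    estimate_offsets,
    feature_fractions,
    footprints_to_frame,
    frame_fractions,
    length_distribution,
    metagene,
    read_footprints_tsv,
    read_transcripts_tsv,
    stalling_fold_change,
    stalling_indexes,
)
from preribo.simulate import RiboSimConfig, sim_ribo, sim_transcriptome, write_ribo_dataset


@pytest.fixture(scope="module")
def tx():
    return {
        "T1.1": TranscriptModel("G1", "T1.1", 400, 60, 360),
        "T2.1": TranscriptModel("G2", "T2.1", 280, 40, 220),
    }


def _track(entries, library_id="lib", offsets=None):
    frame = pd.DataFrame(
        [{"transcript_id": t, "pos": p, "count": float(c)} for (t, p), c in entries.items()]
    )
    if frame.empty:
        frame = pd.DataFrame({"transcript_id": [], "pos": [], "count": []})
    return PsiteTrack(library_id=library_id, frame=frame, offsets=offsets or {28: 12})


class TestTranscriptModel:
    def test_cds_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            TranscriptModel("G", "T", 100, 10, 51)

    def test_cds_must_fit(self):
        with pytest.raises(ValueError, match="outside"):
            TranscriptModel("G", "T", 100, 10, 109)

    def test_tsv_round_trip(self, tmp_path, tx):
        path = tmp_path / "tx.tsv"
        pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in tx.values()],
                "transcript_id": list(tx),
                "length": [t.length for t in tx.values()],
                "cds_start": [t.cds_start + 1 for t in tx.values()],
                "cds_end": [t.cds_end for t in tx.values()],
            }
        ).to_csv(path, sep="\t", index=False)
        assert read_transcripts_tsv(path) == tx


class TestLengthsAndOffsets:
    def test_unimodal_histogram(self):
        fps = [Footprint("T1.1", 0, 28)] * 5 + [Footprint("T1.1", 0, 29)] * 2
        hist, modes = length_distribution(fps)
        assert hist == {28: 5, 29: 2} and modes == [28]

    def test_bimodal_tie_reports_smaller_first(self):
        fps = [Footprint("T1.1", 0, 27)] * 3 + [Footprint("T1.1", 0, 29)] * 3
        _, modes = length_distribution(fps)
        assert modes == [27, 29]

    def test_empty_input(self):
        assert length_distribution([]) == ({}, [])

    def test_planted_offsets_recovered(self, tx):
        rng = np.random.default_rng(2)
        true = {27: 11, 28: 12, 29: 14}
        fps = []
        for length, off in true.items():
            for _ in range(200):
                t = tx["T1.1"] if rng.random() < 0.5 else tx["T2.1"]
                fps.append(Footprint(t.transcript_id, t.cds_start - off, length))
        offsets, flags = estimate_offsets(fps, tx)
        assert offsets == true and flags == {}

    def test_sparse_class_falls_back_with_flag(self, tx):
        fps = [Footprint("T1.1", 10, 26)] * 5
        offsets, flags = estimate_offsets(fps, tx)
        assert offsets[26] == 12 and flags[26] == "sparse_default"

    def test_uninformative_class_tie_breaks_to_12(self, tx):
        fps = [Footprint("T1.1", 200 + i, 28) for i in range(150)]  # deep in CDS
        offsets, flags = estimate_offsets(fps, tx)
        assert offsets[28] == 12 and flags[28] == "tie_default"


class TestPsiteAssignment:
    def test_basic_shift_and_accumulation(self, tx):
        fps = [Footprint("T1.1", 48, 28), Footprint("T1.1", 48, 28)]
        track = assign_psites(fps, {28: 12}, tx)
        assert track.count_at("T1.1", 60) == 2
        assert track.total == 2 and track.dropped == 0

    def test_unmodeled_length_dropped_and_counted(self, tx):
        fps = [Footprint("T1.1", 48, 28), Footprint("T1.1", 48, 35)]
        track = assign_psites(fps, {28: 12}, tx)
        assert track.total == 1 and track.dropped == 1

    def test_count_conservation(self, tx):
        rng = np.random.default_rng(8)
        fps = [
            Footprint("T1.1", int(rng.integers(0, 350)), int(rng.choice([27, 28, 29])))
            for _ in range(500)
        ]
        track = assign_psites(fps, {27: 12, 28: 12, 29: 13}, tx)
        assert track.total + track.dropped == 500


class TestProfilesAndFractions:
    def test_all_counts_at_atg_peak_profile(self, tx):
        track = _track({("T1.1", 60): 7})
        offsets, start, stop = metagene(track, tx)
        assert start[20] == 1.0 and start.sum() == 1.0
        assert stop.sum() == 0.0

    def test_uniform_counts_flat_profile(self, tx):
        entries = {("T1.1", p): 1 for p in range(40, 81)}
        _, start, _ = metagene(_track(entries), tx)
        assert np.allclose(start, 1 / 41)

    def test_frames(self, tx):
        in_frame = {("T1.1", 60 + 3 * k): 1 for k in range(30)}
        assert np.allclose(frame_fractions(_track(in_frame), tx), [1, 0, 0])
        uniform = {("T1.1", 60 + k): 1 for k in range(30)}
        assert np.allclose(frame_fractions(_track(uniform), tx), [1 / 3] * 3)

    def test_feature_fractions(self, tx):
        track = _track({("T1.1", 10): 1, ("T1.1", 100): 2, ("T1.1", 380): 1})
        feats = feature_fractions(track, tx)
        assert feats == {"5'UTR": 0.25, "CDS": 0.5, "3'UTR": 0.25}


class TestStallingIndex:
    def test_simple_ratio(self, tx):
        entries = {("T1.1", 60): 4, ("T1.1", 61): 3, ("T1.1", 62): 3}
        entries.update({("T1.1", 60 + 3 * k): entries.get(("T1.1", 60 + 3 * k), 0) + 3 for k in range(1, 31)})
        track = _track(entries)
        idx = atg_stalling_index(track, tx["T1.1"])
        assert idx == pytest.approx(10 / 100)

    def test_uniform_orf_gives_one_over_codons(self, tx):
        t = tx["T2.1"]
        entries = {(t.transcript_id, t.cds_start + 3 * k): 1 for k in range(60)}
        idx = atg_stalling_index(_track(entries), t)
        assert idx == pytest.approx(1 / 60)

    def test_low_count_is_none(self, tx):
        idx = atg_stalling_index(_track({("T1.1", 60): 3}), tx["T1.1"])
        assert idx is None

    def test_index_bounds(self, tx):
        rng = np.random.default_rng(1)
        entries = {("T1.1", int(p)): int(c) for p, c in
                   zip(rng.integers(60, 360, 50), rng.integers(1, 5, 50))}
        idx = atg_stalling_index(_track(entries), tx["T1.1"])
        assert 0.0 <= idx <= 1.0

    def test_single_nucleotide_mode(self, tx):
        entries = {("T1.1", 60): 4, ("T1.1", 61): 6}
        for k in range(2, 12):
            entries[("T1.1", 60 + 3 * k)] = 1
        track = _track(entries)
        codon = atg_stalling_index(track, tx["T1.1"], codon_level=True)
        nt = atg_stalling_index(track, tx["T1.1"], codon_level=False)
        assert codon == pytest.approx(10 / 20)
        assert nt == pytest.approx(4 / 20)


class TestFoldChange:
    def test_identical_genotypes(self):
        idx = {f"G{i}": 0.1 + 0.01 * i for i in range(30)}
        st = stalling_fold_change(idx, dict(idx))
        assert st.median_fc == 1.0
        assert math.isnan(st.p_value)  # all log2 FC exactly 0: degenerate
        assert "degenerate_variance" in st.flags

    def test_constant_doubling_is_degenerate_with_median_two(self):
        wt = {f"G{i}": 0.05 + 0.001 * i for i in range(20)}
        mut = {g: 2 * v for g, v in wt.items()}
        st = stalling_fold_change(mut, wt)
        assert st.median_fc == pytest.approx(2.0)
        assert "degenerate_variance" in st.flags

    def test_zero_wt_index_excluded(self):
        wt = {"G0": 0.0, "G1": 0.1, "G2": 0.1}
        mut = {"G0": 0.2, "G1": 0.2, "G2": 0.2}
        st = stalling_fold_change(mut, wt)
        assert st.n_genes == 2 and st.n_excluded == 1

    def test_one_sided_test_detects_amplification(self):
        rng = np.random.default_rng(6)
        wt = {f"G{i}": float(v) for i, v in enumerate(rng.uniform(0.02, 0.2, 200))}
        mut = {g: v * float(np.exp(rng.normal(np.log(2.0), 0.2))) for g, v in wt.items()}
        st = stalling_fold_change(mut, wt)
        assert st.median_fc == pytest.approx(2.0, rel=0.15)
        assert st.p_value < 1e-6
        assert st.method == "t_one_sample_log2fc"

    def test_low_gene_count_flagged(self):
        st = stalling_fold_change({"G1": 0.2, "G2": 0.3}, {"G1": 0.1, "G2": 0.2})
        assert "low_power" in st.flags

    def test_replicate_averaging(self):
        r1 = {"G1": 0.1, "G2": None}
        r2 = {"G1": 0.3, "G2": 0.2}
        avg = average_replicates([r1, r2])
        assert avg == {"G1": 0.2, "G2": None}


class TestSimulatorRoundTrip:
    def test_truth_index_matches_pipeline_exactly(self):
        config = RiboSimConfig(n_genes=40, stall_median=3.0, depth_per_gene=300)
        fps, truth, tx_models = sim_ribo(config, 11)
        track = assign_psites(fps, config.offsets, tx_models)
        idx = stalling_indexes(track, tx_models, min_counts=1)
        for row in truth.itertuples(index=False):
            assert idx[row.gene_id] == pytest.approx(row.true_index)

    def test_written_dataset_reloads(self, tmp_path):
        config = RiboSimConfig(n_genes=10, depth_per_gene=50)
        fp_path, tx_path, truth_path = write_ribo_dataset(tmp_path, config, 3)
        fps = read_footprints_tsv(fp_path)
        tx_models = read_transcripts_tsv(tx_path)
        direct, _, _ = sim_ribo(config, 3)
        assert len(fps) == len(direct)
        assert (fps["five_prime"].to_numpy() == direct["five_prime"].to_numpy()).all()
        assert set(fps["transcript_id"].unique()) <= set(tx_models)
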