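"""The synthetic-data generator: planted ground truth, determinism, count model."""

from __future__ import annotations

import numpy as np
import pytest

from tissense.simulate import (
    NEAR_COGNATE_CODONS,
    SimConfig,
    SimulationError,
    generate_transcriptome,
    plant_antigens,
    simulate_footprints,
)

from _oracles import orf_from


def test_generation_is_pure_function_of_seed(small_config, small_world, small_footprints):
    tset2, truth2 = generate_transcriptome(small_config)
    tset, truth = small_world
    assert tset == tset2
    assert truth.planted == truth2.planted
    assert truth.expression == truth2.expression
    fps2 = simulate_footprints(tset, truth, small_config, seed=11)
    assert small_footprints.df.equals(fps2.df)


def test_planted_orfs_honour_positional_class_definitions(small_world):
    tset, truth = small_world
    start_codons = {"ATG"}
    for p in truth.planted:
        rec = tset[p.transcript_id]
        assert rec.sequence[p.tis : p.tis + 3] in start_codons
        if p.orf_class == "lncRNA":
            assert not rec.is_coding
            continue
        frame = (p.tis - rec.cds_start) % 3
        if p.orf_class == "annotated":
            assert p.tis == rec.cds_start
        elif p.orf_class == "upstream":
            assert p.tis < rec.cds_start
            assert p.stop + 3 <= rec.cds_start  # wholly within the 5'UTR by default
        elif p.orf_class == "downstream":
            assert p.tis >= rec.cds_end
        elif p.orf_class == "internal_in_frame":
            assert rec.cds_start < p.tis < rec.cds_end and frame == 0
        elif p.orf_class == "internal_out_of_frame":
            assert rec.cds_start < p.tis < rec.cds_end and frame != 0
        else:
            raise AssertionError(p.orf_class)


def test_retranslating_planted_tis_reproduces_recorded_peptide_and_stop(small_world):
    tset, truth = small_world
    for p in truth.planted:
        stop, peptide = orf_from(tset[p.transcript_id].sequence, p.tis)
        assert stop == p.stop, p
        assert peptide == p.peptide, p


def test_zero_length_utr5_puts_cds_at_position_zero():
    cfg = SimConfig(
        n_coding_transcripts=4,
        n_lncrna_transcripts=0,
        utr5_length_range=(0, 0),
        planted_orf_mix={"internal_in_frame": 1},
        seed=3,
    )
    tset, _ = generate_transcriptome(cfg)
    assert all(rec.cds_start == 0 for rec in tset.values())


def test_pure_lncrna_transcriptome_has_no_cds():
    cfg = SimConfig(n_coding_transcripts=0, n_lncrna_transcripts=5, seed=4)
    tset, truth = generate_transcriptome(cfg)
    assert len(tset) == 5
    assert all(rec.biotype == "lncRNA" and rec.cds_start is None for rec in tset.values())
    assert all(p.orf_class == "lncRNA" for p in truth.planted)


def test_infeasible_uorf_request_raises_naming_the_constraint():
    with pytest.raises(SimulationError, match="utr5_length_range"):
        SimConfig(utr5_length_range=(0, 20), planted_orf_mix={"upstream": 1})


def test_near_cognate_mode_uses_single_substitution_neighbours_of_atg():
    assert len(NEAR_COGNATE_CODONS) == 9
    assert all(sum(a != b for a, b in zip(c, "ATG")) == 1 for c in NEAR_COGNATE_CODONS)
    cfg = SimConfig(
        n_coding_transcripts=6, n_lncrna_transcripts=0, start_codon_mode="near_cognate", seed=9
    )
    tset, truth = generate_transcriptome(cfg)
    allowed = set(NEAR_COGNATE_CODONS) | {"ATG"}
    starts = {
        tset[p.transcript_id].sequence[p.tis : p.tis + 3]
        for p in truth.planted
        if p.orf_class in ("upstream", "downstream")
    }
    assert starts <= allowed and starts - {"ATG"}  # at least one near-cognate drawn


def test_uorf_overlap_option_extends_uorfs_out_of_frame_into_cds():
    cfg = SimConfig(
        n_coding_transcripts=6,
        n_lncrna_transcripts=0,
        uorf_overlap_cds=True,
        planted_orf_mix={"upstream": 1},
        seed=12,
    )
    tset, truth = generate_transcriptome(cfg)
    ups = truth.by_class("upstream")
    assert ups
    for p in ups:
        rec = tset[p.transcript_id]
        assert p.tis < rec.cds_start < p.stop
        assert (p.tis - rec.cds_start) % 3 != 0


class TestAntigenCatalog:
    def test_epitopes_are_in_frame_substrings_of_source_peptides(self, small_world):
        tset, truth = small_world
        catalog = plant_antigens(
            tset,
            truth,
            class_mix={"annotated": 3, "upstream": 3, "out_of_frame": 3, "alternative": 3, "lncRNA": 2},
            seed=5,
        )
        assert len(catalog) == 14
        for ag in catalog:
            _, peptide = orf_from(tset[ag.transcript_id].sequence, ag.expected_tis)
            assert ag.epitope in peptide
            assert len(ag.epitope) == 9

    def test_impossible_class_request_errors(self):
        cfg = SimConfig(n_coding_transcripts=0, n_lncrna_transcripts=3, seed=2)
        tset, truth = generate_transcriptome(cfg)
        with pytest.raises(ValueError, match="annotated"):
            plant_antigens(tset, truth, class_mix={"annotated": 1}, seed=0)


class TestFootprintModel:
    def test_same_seed_gives_identical_footprints(self, small_config, small_world):
        tset, truth = small_world
        a = simulate_footprints(tset, truth, small_config, seed=42)
        b = simulate_footprints(tset, truth, small_config, seed=42)
        assert a.df.equals(b.df)

    def test_extreme_enrichment_concentrates_psites_on_active_tis(self, small_config, small_world):
        tset, truth = small_world
        cfg = SimConfig(
            **{**small_config.__dict__, "initiation_enrichment": 1e9, "total_reads": 20_000}
        )
        fps = simulate_footprints(tset, truth, cfg, seed=1)
        tis_positions = {
            (p.transcript_id, p.tis + j) for p in truth.planted for j in range(3)
        }
        offsets = cfg.offset_map
        psites = [
            (row.transcript_id, row.five_prime_pos + offsets[row.read_length])
            for row in fps.df.itertuples()
        ]
        on_tis = sum(ps in tis_positions for ps in psites)
        assert on_tis / len(psites) > 0.999

    def test_background_mean_matches_configured_intensity(self, small_world):
        tset, truth = small_world
        cfg = SimConfig(
            n_coding_transcripts=10,
            n_lncrna_transcripts=3,
            total_reads=60_000,
            nb_dispersion=5.0,
            seed=7,
        )
        fps = simulate_footprints(tset, truth, cfg, active_tis=set(), seed=21)
        # with no active TIS every position is background with mu_i = c * w_t
        weights = {tid: truth.expression[tset[tid].gene_id] for tid in tset}
        total_intensity = sum(w * tset[tid].length for tid, w in weights.items())
        scale = cfg.total_reads / total_intensity
        tid = max(weights, key=weights.get)
        n = tset[tid].length
        mu = scale * weights[tid]
        # count P-sites (5' + offset) rather than 5' ends to avoid edge losses
        sub = fps.df[fps.df.transcript_id == tid]
        observed = len(sub) / n
        var = mu + mu * mu / cfg.nb_dispersion
        se = np.sqrt(var / n)
        assert abs(observed - mu) < 3 * se + 0.02 * mu

    def test_counts_are_negative_binomially_dispersed(self, small_world):
        tset, truth = small_world
        cfg = SimConfig(
            n_coding_transcripts=10,
            n_lncrna_transcripts=3,
            total_reads=200_000,
            nb_dispersion=2.0,
            expression_log10_sd=0.0,  # flat expression: iid counts per nt
            seed=7,
        )
        _, flat_truth = generate_transcriptome(cfg)
        fps = simulate_footprints(tset, flat_truth, cfg, active_tis=set(), seed=33)
        counts = np.zeros(sum(r.length for r in tset.values()))
        offset = 0
        for tid, rec in tset.items():
            sub = fps.df[fps.df.transcript_id == tid]
            pos = sub.five_prime_pos.to_numpy() + sub.read_length.map(cfg.offset_map).to_numpy()
            np.add.at(counts, offset + pos[pos < rec.length], 1)
            offset += rec.length
        mu, var = counts.mean(), counts.var(ddof=1)
        assert var > mu  # overdispersed
        k_hat = mu * mu / (var - mu)
        assert 0.5 * cfg.nb_dispersion < k_hat < 2.0 * cfg.nb_dispersion

    def test_missing_offset_for_sampled_length_is_an_error(self):
        with pytest.raises(SimulationError, match="offset"):
            SimConfig(read_length_weights={27: 1.0})
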