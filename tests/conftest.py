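from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tissense.io import TranscriptRecord, TranscriptSet
from tissense.simulate import SimConfig, generate_transcriptome, simulate_footprints

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_coding_transcripts=10, n_lncrna_transcripts=3, total_reads=40_000, seed=7
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    tset, truth = generate_transcriptome(small_config)
    return tset, truth


@pytest.fixture(scope="session")
def small_footprints(small_config, small_world):
    tset, truth = small_world
    return simulate_footprints(tset, truth, small_config, seed=11)


def make_uorf_transcript() -> tuple[TranscriptRecord, int, str]:
    """A transcript carrying a 26-aa uORF starting 267 nt upstream of the CDS.

    Returns (record, uorf_tis, epitope) where the epitope is the first 9 aa
    of the uORF peptide.
    """
    uorf_tis = 10
    body_codons = ["GCT", "TTC", "GGA", "AAA", "CCT"] * 5  # 25 codons
    uorf = "ATG" + "".join(body_codons) + "TAA"  # 26 aa + stop = 81 nt
    cds_start = uorf_tis + 267
    utr5 = "C" * uorf_tis + uorf + "G" * (cds_start - uorf_tis - len(uorf))
    cds = "ATG" + "GAA" * 40 + "TGA"
    seq = utr5 + cds + "T" * 50
    rec = TranscriptRecord(
        transcript_id="TX_UORF",
        gene_id="GENE_UORF",
        biotype="coding",
        sequence=seq,
        cds_start=cds_start,
        cds_end=cds_start + len(cds),
    )
    peptide = "M" + "AFGKP" * 5
    return rec, uorf_tis, peptide[:9]


@pytest.fixture
def uorf_transcript():
    return make_uorf_transcript()


def lnc_record(seq: str, tid: str = "L1", gid: str = "G1") -> TranscriptRecord:
    return TranscriptRecord(transcript_id=tid, gene_id=gid, biotype="lncRNA", sequence=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
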