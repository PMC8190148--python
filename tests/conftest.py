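import datetime as dt

import pandas as pd
import pytest

from mareta import simulate
from mareta.quantify import ContigRecord, SampleMeta


@pytest.fixture(scope="session")
def community_sim():
    """Planted 500-contig / 20-MAG / 25-month community (fixed seed)."""
    return simulate.simulate_community_timeseries(seed=11)


@pytest.fixture(scope="session")
def pfam_sim():
    """50 references, 100 domains, 200 thinned queries (fixed seed)."""
    return simulate.simulate_pfam_profiles(seed=7)


@pytest.fixture()
def two_samples():
    return [
        SampleMeta("s1", "C5", dt.date(2012, 4, 15), "SUF", "0.2-0.8",
                   water_volume_L=4.0, total_dna_g=5e-8, total_reads=1000),
        SampleMeta("s2", "C5", dt.date(2012, 5, 15), "SUF", "0.2-0.8",
                   water_volume_L=2.0, total_dna_g=2e-8, total_reads=2000),
    ]


@pytest.fixture()
def three_contigs():
    return [
        ContigRecord("c1", 1000),
        ContigRecord("c2", 500),
        ContigRecord("c3", 2000),
    ]


def make_alignments(rows):
    return pd.DataFrame(rows, columns=["read_id", "contig_id", "sample_id", "identity"])
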