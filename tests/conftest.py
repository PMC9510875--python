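"""Shared fixtures: small hand-built records, profiles and input files."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from ptmdyn.io_tables import SiteQuantRecord
from ptmdyn.site_processing import TemporalProfile


def make_profile(
    m05: float | None,
    m2: float | None,
    accession: str = "P1",
    position: int = 10,
    ptm_type: str = "phospho",
    condition: str = "untreated",
) -> TemporalProfile:
    return TemporalProfile(
        accession=accession,
        position=position,
        ptm_type=ptm_type,
        condition=condition,
        residue="S",
        mean_log2_05h=m05,
        mean_log2_2h=m2,
        n_05h=0 if m05 is None else 3,
        n_2h=0 if m2 is None else 3,
    )


def make_record(
    accession: str = "P1",
    position: int = 10,
    ptm_type: str = "phospho",
    log2_ml=(1.0, 1.0, 1.0),
    log2_hl=(0.0, 0.0, 0.0),
    loc_prob: float | None = 0.99,
    condition: str = "untreated",
    residue: str = "S",
    intensity: float = 1000.0,
) -> SiteQuantRecord:
    return SiteQuantRecord(
        accession=accession,
        position=position,
        residue=residue,
        ptm_type=ptm_type,
        loc_prob=loc_prob,
        log2_ml=list(log2_ml),
        log2_hl=list(log2_hl),
        intensity=intensity,
        condition=condition,
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def site_table_file(tmp_path):
    """A well-formed three-row site table, including one missing ratio cell
    and one sub-threshold localization probability."""
    path = tmp_path / "sites.tsv"
    header = (
        "accession\tposition\tresidue\tloc_prob\t"
        "log2_ML_rep1\tlog2_ML_rep2\tlog2_ML_rep3\t"
        "log2_HL_rep1\tlog2_HL_rep2\tlog2_HL_rep3\t"
        "intensity\tcondition\n"
    )
    rows = [
        "P1\t10\tS\t0.99\t1.5\t0.9\t1.2\t0.1\t0.2\t0.0\t5000.0\tuntreated\n",
        "P1\t25\tT\t0.85\t0.5\tNA\t0.4\t1.1\t1.0\t\t4000.0\tuntreated\n",
        "P2\t7\tY\t0.95\t-1.2\t-1.1\t-1.3\t-0.1\t0.1\t0.0\t3000.0\tuntreated\n",
    ]
    path.write_text(header + "".join(rows), encoding="utf-8")
    return path
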