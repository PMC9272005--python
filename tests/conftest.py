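import pytest

from glyi.catalog import DomainSpan, ProteinRecord, load_catalog
from glyi.classify import builtin_profiles, site_results_from_table
from glyi.synthetic import fixture_path


@pytest.fixture(scope="session")
def family_catalog():
    return load_catalog(fixture_path("table1"))


@pytest.fixture(scope="session")
def site_table_results():
    return site_results_from_table(fixture_path("table2"))


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


def protein_from_domain(pid: str, domain: str, nflank: str = "",
                        cflank: str = "") -> ProteinRecord:
    """Wrap a domain sequence (optionally flanked) into a ProteinRecord."""
    seq = nflank + domain + cflank
    start = len(nflank) + 1
    return ProteinRecord(
        protein_id=pid, length=len(seq), sequence=seq,
        domains=[DomainSpan(length=len(domain), start=start,
                            end=start + len(domain) - 1)],
    )
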