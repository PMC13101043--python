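import pandas as pd
import pytest

import n2kgap as g


@pytest.fixture(scope="session")
def worked():
    """The six-site worked fixture and its hand-computed expectations."""
    sites, habitats, bioregions, expected = g.make_worked_fixture()
    return {
        "sites": sites,
        "habitats": habitats,
        "bioregions": bioregions,
        "expected": expected,
    }


@pytest.fixture(scope="session")
def worked_bundle(worked):
    return g.run_pipeline(
        sites=worked["sites"],
        habitats=worked["habitats"],
        bioregions=worked["bioregions"],
    )


@pytest.fixture(scope="session")
def taxonomy():
    return g.load_taxonomy()


@pytest.fixture(scope="session")
def crosswalk():
    links, rl_regions = g.load_crosswalk()
    return links, rl_regions


@pytest.fixture
def sites_csv(tmp_path):
    """Write a small raw NATURA2000SITES export and return its path."""

    def _write(rows, header="SITECODE,SITETYPE,AREAHA,COUNTRY_CODE"):
        path = tmp_path / "sites.csv"
        path.write_text("\n".join([header, *rows]) + ("\n" if rows else "\n"))
        return path

    return _write


@pytest.fixture
def habitats_csv(tmp_path):
    def _write(rows, header="SITECODE,HABITATCODE,COVER_HA"):
        path = tmp_path / "habitats.csv"
        path.write_text("\n".join([header, *rows]) + ("\n" if rows else "\n"))
        return path

    return _write


@pytest.fixture
def bioregions_csv(tmp_path):
    def _write(rows, header="SITECODE,BIOGEFRAPHICREG,PERCENTAGE"):
        path = tmp_path / "bioregions.csv"
        path.write_text("\n".join([header, *rows]) + ("\n" if rows else "\n"))
        return path

    return _write


def canonical_sites(rows):
    """rows: (site_code, site_type, total_area_ha, country)"""
    return pd.DataFrame(rows, columns=["site_code", "site_type", "total_area_ha", "country"])


def canonical_habitats(rows):
    """rows: (site_code, habitat_code, priority, cover_ha)"""
    return pd.DataFrame(rows, columns=["site_code", "habitat_code", "priority", "cover_ha"])


def canonical_bioregions(rows):
    """rows: (site_code, region, percent_of_site)"""
    return pd.DataFrame(rows, columns=["site_code", "region", "percent_of_site"])
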