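import numpy as np
import pytest

import equipanel as ep


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel shared across read-only tests."""
    return ep.generate_panel(ep.GeneratorConfig(seed=42))


@pytest.fixture
def small_panel_frame():
    """A tiny 3-region x 2-year well-formed frame builder."""
    import pandas as pd

    def build(overrides=None):
        overrides = overrides or {}
        rows = []
        for rid, zone, pop, area in [
            ("A", "eastern", 10.0, 100.0),
            ("B", "central", 20.0, 50.0),
            ("C", "western", 30.0, 200.0),
        ]:
            for year in (2003, 2004):
                row = {
                    "region_id": rid,
                    "zone": zone,
                    "year": year,
                    "population": pop,
                    "area_km2": area,
                    "cmhi_institution": 1.0,
                    "cmhi_bed": pop * 2,
                    "cmhi_personnel": pop * 3,
                    "th_institution": 2.0,
                    "th_bed": pop,
                    "th_personnel": pop * 1.5,
                    "vc_institution": 5.0,
                    "vc_personnel": pop,
                }
                row.update(overrides.get((rid, year), {}))
                rows.append(row)
        return pd.DataFrame(rows)

    return build


def random_allocation(rng, n=None, zones=3):
    """Random positive allocation used by the oracle/property suites."""
    n = n or rng.integers(2, 51)
    m = rng.uniform(0.1, 10.0, size=n)
    e = rng.uniform(0.05, 10.0, size=n)
    zone_labels = [f"z{rng.integers(zones)}" for _ in range(n)]
    return ep.AllocationVector(
        region_ids=tuple(f"r{i:03d}" for i in range(n)),
        zones=tuple(zone_labels),
        m=m,
        e=e,
        calibre=ep.Calibre.POPULATION,
    )
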