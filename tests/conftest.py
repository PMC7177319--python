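import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mapssn.audit_model import load_scheme
from mapssn.network_buffer import StreetNetwork

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return load_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170901)


@pytest.fixture()
def path_network():
    """O -- A -- B chain: 300 m + 300 m."""
    return StreetNetwork.from_lines([
        ("main", [(0.0, 0.0), (300.0, 0.0), (600.0, 0.0)]),
        ("stub", [(300.0, 0.0), (300.0, 50.0)]),  # makes A an endpoint junction
    ])


@pytest.fixture()
def grid_network():
    """4x4 junction grid with 100 m edges (toy oracle graph)."""
    lines = []
    for r in range(4):
        lines.append((f"R{r}", [(100.0 * c, 100.0 * r) for c in range(4)]))
    for c in range(4):
        lines.append((f"C{c}", [(100.0 * c, 100.0 * r) for r in range(4)]))
    return StreetNetwork.from_lines(lines)


def best_case_record(scheme, unit_kind, unit_id="S01.X.01.O", school="S01"):
    """Audit record with every positive item at its best recode and every
    negative item at its least-penalising recode."""
    from mapssn.audit_model import AuditRecord
    values = {}
    for item in scheme.items_for(unit_kind):
        sub = scheme.subscale_of(item.name)
        values[item.name] = (item.best_raw if sub.valence == "positive"
                             else item.worst_raw)
    return AuditRecord(unit_kind=unit_kind, unit_id=unit_id,
                       school_id=school, item_values=values)
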