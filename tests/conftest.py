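import math

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: reconciled per-library clone counts of the six-library copepod study
TABLE1_COUNTS = {
    "Cipr": (2, 24, 2, 2),
    "Sulf": (2, 20, 4, 4),
    "Trim": (3, 22, 2, 3),
    "SS": (15, 6, 2, 3, 4),
    "Ac": (18, 3, 2, 2, 5),
    "DMSO": (19, 4, 2, 5),
}

#: printed per-library diversity values (H_B in nats, 2 dp)
TABLE2_HB = {"Cipr": 0.59, "Sulf": 0.84, "Trim": 0.73, "SS": 1.15, "Ac": 1.01, "DMSO": 0.89}


@pytest.fixture(scope="session")
def table1_counts():
    return TABLE1_COUNTS


def brillouin_oracle(counts) -> float:
    """Exact big-integer Brillouin diversity, independent of the package."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    return (
        math.log(math.factorial(n)) - sum(math.log(math.factorial(c)) for c in counts)
    ) / n


def compositions(n: int, s: int):
    """All ordered compositions of n into s positive parts."""
    if s == 1:
        yield (n,)
        return
    for first in range(1, n - s + 2):
        for rest in compositions(n - first, s - 1):
            yield (first,) + rest
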