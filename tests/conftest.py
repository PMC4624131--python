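import math
import random

import pytest

from lbrscan import (
    DEFAULT_SCALE,
    Label,
    NearFlag,
    PeptideWindow,
    WindowMetrics,
    discrimination_factor,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_moment(sequence: str, scale=DEFAULT_SCALE, delta_deg: float = 100.0) -> float:
    """Independent oracle: explicit pure-Python loop over cos/sin terms."""
    x = y = 0.0
    for n, residue in enumerate(sequence):
        h = scale.values[residue]
        x += h * math.cos(math.radians(n * delta_deg))
        y += h * math.sin(math.radians(n * delta_deg))
    return math.sqrt(x * x + y * y) / len(sequence)


def random_peptide(rng: random.Random, min_len: int = 2, max_len: int = 30) -> str:
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def make_metrics(mean_h: float, mu_h: float, z: int) -> WindowMetrics:
    """Build a WindowMetrics with chosen plot coordinates (dummy window)."""
    return WindowMetrics(
        window=PeptideWindow("A" * 18),
        mean_h=mean_h,
        mu_h=mu_h,
        z=z,
        d=discrimination_factor(mu_h, z),
    )


@pytest.fixture
def seeded_rng() -> random.Random:
    return random.Random(20240918)
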