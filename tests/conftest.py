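import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trawlsel import CatchDataset, HaulRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_haul(
    haul_id="h1",
    treatment="A",
    lengths=(18, 19, 20, 21, 22),
    n_codend=(2, 5, 10, 15, 18),
    n_cover=(18, 15, 10, 5, 2),
    q_codend=1.0,
    q_cover=1.0,
    meta=None,
):
    return HaulRecord(
        haul_id=haul_id,
        treatment=treatment,
        length_classes=np.array(lengths),
        n_codend=np.array(n_codend),
        n_cover=np.array(n_cover),
        q_codend=q_codend,
        q_cover=q_cover,
        meta=meta or {},
    )


@pytest.fixture
def toy_dataset():
    """Two-haul dataset with subsampling, small enough for hand checks."""
    return CatchDataset(
        [
            make_haul("h1", q_codend=0.5, q_cover=0.8),
            make_haul(
                "h2",
                lengths=(19, 20, 21, 22, 23),
                n_codend=(3, 8, 12, 14, 15),
                n_cover=(12, 9, 6, 3, 1),
                q_codend=1.0,
                q_cover=0.25,
            ),
        ]
    )


def random_small_dataset(rng: np.random.Generator) -> CatchDataset:
    """A random 1-3 haul dataset with <= 8 classes and modest counts."""
    n_hauls = int(rng.integers(1, 4))
    lo = int(rng.integers(12, 20))
    n_classes = int(rng.integers(2, 9))
    hauls = []
    for j in range(n_hauls):
        nR = rng.integers(0, 20, size=n_classes)
        nE = rng.integers(0, 20, size=n_classes)
        if nR.sum() + nE.sum() == 0:
            nR[0] = 1
        hauls.append(
            HaulRecord(
                haul_id=f"h{j}",
                treatment="A",
                length_classes=np.arange(lo, lo + n_classes),
                n_codend=nR,
                n_cover=nE,
                q_codend=float(rng.uniform(0.05, 1.0)),
                q_cover=float(rng.uniform(0.05, 1.0)),
            )
        )
    return CatchDataset(hauls)
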