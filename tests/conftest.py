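import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from micromiss.tables_io import DetectionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170523)


def make_matrix(presence: dict[str, dict[str, bool]], groups: dict[str, str],
                modality: str = "culturomics") -> DetectionMatrix:
    """Build a DetectionMatrix from nested {sample: {species: bool}} dicts."""
    df = pd.DataFrame.from_dict(presence, orient="index").fillna(False).astype(bool)
    return DetectionMatrix(modality=modality, presence=df, groups=pd.Series(groups))


@pytest.fixture
def small_matrix() -> DetectionMatrix:
    """3 cases + 2 controls over five species with known column sums."""
    return make_matrix(
        {
            "k1": {"A": True, "B": True, "C": False, "D": False, "E": True},
            "k2": {"A": True, "B": False, "C": True, "D": False, "E": False},
            "k3": {"A": True, "B": False, "C": False, "D": False, "E": False},
            "c1": {"A": True, "B": True, "C": True, "D": True, "E": False},
            "c2": {"A": False, "B": True, "C": False, "D": False, "E": True},
        },
        {"k1": "case", "k2": "case", "k3": "case", "c1": "control", "c2": "control"},
    )
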