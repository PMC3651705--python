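from pathlib import Path

import numpy as np
import pytest
import yaml
from hypothesis import strategies as st

from tubopt import (CancerContext, IsotypeProfile, N_ISOTYPES,
                    PatientCharacteristics, demo_panel, normalize,
                    write_expression_table)


def profile_strategy(min_support: int = 1):
    """Hypothesis strategy for valid 8-isotype profiles."""

    def build(raw):
        v = np.array(raw)
        if np.count_nonzero(v) < min_support:
            v[:min_support] = v[:min_support] + 1.0
        return normalize(v)

    return st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=N_ISOTYPES, max_size=N_ISOTYPES,
    ).filter(lambda xs: sum(xs) > 1e-6).map(build)


@pytest.fixture
def worked_instance():
    """The hand-derived 3-isotype LP instance with known solution."""
    q_c = normalize([0.6, 0.3, 0.1, 0, 0, 0, 0, 0], "cancer")
    q_h = normalize([0.8, 0.1, 0.1, 0, 0, 0, 0, 0], "healthy")
    expected_r = np.array([1 / 7, 6 / 7, 0, 0, 0, 0, 0, 0])
    return q_c, q_h, 0.2, expected_r, 12 / 35


@pytest.fixture(scope="session")
def demo():
    cancer, healthy, cfg = demo_panel()
    return cancer, healthy, cfg


@pytest.fixture
def demo_files(demo, tmp_path: Path):
    """Demo panel written out as CLI-consumable files."""
    cancer, healthy, cfg = demo
    paths = {
        "cancer": tmp_path / "cancer.tsv",
        "healthy": tmp_path / "healthy.tsv",
        "weights": tmp_path / "weights.yaml",
    }
    write_expression_table(cancer, paths["cancer"])
    write_expression_table(healthy, paths["healthy"])
    paths["weights"].write_text(yaml.safe_dump(cfg.model_dump(mode="json")))
    return paths


def male_iv_context(cancer: str = "cancer") -> CancerContext:
    return CancerContext(cancer, "iv", PatientCharacteristics("male"))


def random_profile(rng: np.random.Generator, support: int = N_ISOTYPES,
                   label: str = "") -> IsotypeProfile:
    """Dirichlet profile on the first ``support`` isotypes."""
    v = np.zeros(N_ISOTYPES)
    v[:support] = rng.dirichlet(np.ones(support))
    return IsotypeProfile(v, label)
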