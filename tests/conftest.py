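import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loopanchor.features import FeatureRow
from loopanchor.io import Genome, SequenceRecord
from loopanchor.pipeline import build_feature_rows
from loopanchor.simulate import (
    SimConfig,
    default_null_config,
    default_strong_config,
    simulate,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

SUITE_SEED = 0


def make_genome(seqs: dict[str, str]) -> Genome:
    return Genome([SequenceRecord(k, v) for k, v in seqs.items()])


def random_feature_rows(n: int, positions: int = 59, effect: float = 0.0,
                        seed: int = 0) -> list[FeatureRow]:
    """Quick synthetic FeatureRows: random one-hot windows plus a normal
    intensity shifted by ``effect`` for the positive half."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        label = int(i < n // 2)
        onehot = np.zeros(4 * positions, dtype=np.int8)
        onehot[4 * np.arange(positions) + rng.integers(0, 4, positions)] = 1
        rows.append(
            FeatureRow(
                site_id=f"s{i}",
                onehot=onehot,
                intensity=float(rng.normal(effect * label, 1.0)),
                label=label,
            )
        )
    return rows


@pytest.fixture(scope="session")
def strong_sim(tmp_path_factory):
    return simulate(default_strong_config(seed=SUITE_SEED),
                    tmp_path_factory.mktemp("strong_sim"))


@pytest.fixture(scope="session")
def strong_pipeline(strong_sim):
    return build_feature_rows(
        strong_sim.fasta_path, strong_sim.narrowpeak_path,
        strong_sim.loops_path, strong_sim.pwm_path,
    )


@pytest.fixture(scope="session")
def intensity_dominated_pipeline(tmp_path_factory):
    """Conditions where binding intensity carries nearly all the signal:
    the usual 2-unit log2 intensity shift but a nearly flat flank tilt."""
    cfg = SimConfig(seed=SUITE_SEED, n_sites=1000, flank_bias=0.02)
    res = simulate(cfg, tmp_path_factory.mktemp("intensity_dom"))
    return build_feature_rows(res.fasta_path, res.narrowpeak_path,
                              res.loops_path, res.pwm_path)


@pytest.fixture(scope="session")
def null_sim(tmp_path_factory):
    return simulate(default_null_config(seed=SUITE_SEED),
                    tmp_path_factory.mktemp("null_sim"))


@pytest.fixture(scope="session")
def null_pipeline(null_sim):
    return build_feature_rows(
        null_sim.fasta_path, null_sim.narrowpeak_path,
        null_sim.loops_path, null_sim.pwm_path,
    )
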