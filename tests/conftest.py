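import pytest

from compendia.model import (
    Measurement,
    ParsedExperiment,
    Platform,
    PlatformKind,
    Reporter,
    Sample,
)
from compendia.store import create_compendium


@pytest.fixture
def compendium(tmp_path):
    c = create_compendium("test", tmp_path / "store")
    yield c
    c.close()


def make_toy_parsed(
    experiment_id="exp1",
    platform_id="platA",
    n_samples=2,
    n_reporters=4,
):
    """A minimal clean staged experiment: n_samples x n_reporters."""
    reporters = [Reporter(id=f"r{i + 1}", sequence="ACGT" * 6 + "A") for i in range(n_reporters)]
    platform = Platform(id=platform_id, kind=PlatformKind.microarray, reporters=reporters)
    samples = [
        Sample(
            name=f"s{j + 1}",
            experiment_id=experiment_id,
            platform_id=platform_id,
            measurements=[
                Measurement(key=r.id, value=float(10 * (j + 1) + i))
                for i, r in enumerate(reporters)
            ],
        )
        for j in range(n_samples)
    ]
    return ParsedExperiment(
        experiment_id=experiment_id,
        metadata={"title": "toy"},
        platform=platform,
        samples=samples,
    )


@pytest.fixture
def toy_parsed():
    return make_toy_parsed()


@pytest.fixture
def soft_dataset(tmp_path):
    """On-disk SOFT + probe table + value tables, plus the expected staged
    experiment."""
    from compendia.synthetic import generate_soft_experiment

    soft, probe, vals, expected = generate_soft_experiment(2, 4, seed=7)
    d = tmp_path / "files"
    d.mkdir()
    (d / "exp.soft").write_text(soft)
    (d / "probes.tsv").write_text(probe)
    for name, text in vals.items():
        (d / f"{name}.tsv").write_text(text)
    return d, expected
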