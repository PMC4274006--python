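import numpy as np
import pytest

from snptyper import pipeline, synth
from snptyper.traceqc import QualityRead


def random_read(rng: np.random.Generator, n: int | None = None, read_id: str = "r") -> QualityRead:
    """A random read with block-structured quality (good/bad stretches),
    occasional ambiguity codes, and random secondary fractions."""
    if n is None:
        n = int(rng.integers(30, 400))
    qv = np.empty(n, dtype=int)
    i = 0
    while i < n:
        block = int(rng.integers(5, 60))
        level = int(rng.choice([5, 15, 25, 35, 50]))
        qv[i : i + block] = np.clip(level + rng.integers(-4, 5, size=min(block, n - i)), 0, 60)
        i += block
    bases = rng.choice(list("ACGT"), size=n)
    amb = rng.random(n) < 0.03
    bases[amb] = "N"
    return QualityRead(
        read_id=read_id,
        sample_id="S",
        locus_id="L",
        direction="forward",
        bases="".join(bases),
        qv=tuple(int(q) for q in qv),
        secondary_fraction=tuple(float(x) for x in rng.random(n)),
    )


@pytest.fixture(scope="session")
def default_truth() -> synth.PanelTruth:
    return synth.make_panel(seed=11)


@pytest.fixture(scope="session")
def noiseless_run() -> pipeline.RunResult:
    """Full pipeline on the default noiseless panel (29 samples, 35
    planted SNPs); shared across modules because it is the expensive
    fixture."""
    cfg = pipeline.RunConfig(seed=1, bootstrap_reps=20)
    return pipeline.run_all(cfg)


@pytest.fixture()
def small_config() -> pipeline.RunConfig:
    """Scaled-down panel for fast end-to-end checks."""
    return pipeline.RunConfig(
        seed=3,
        n_samples_per_species=(6, 2, 4),
        n_snps_per_locus={"ITS": 8, "LSU_D1-D3": 5, "rbcL": 2, "matK": 1, "trnH-psbA": 0},
        bootstrap_reps=5,
    )
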