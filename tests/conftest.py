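import hashlib
import time
from pathlib import Path

import numpy as np
import pytest

from cfaekit.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def mini_cohort():
    """4-patient two-class cohort over all six sites (the smoke fixture)."""
    from cfaekit.synthetic import generate_cohort, SITES

    return generate_cohort(2, 2, SITES, seed=17)


def _bundle_hashes(outdir: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
        if p.is_file()
    }


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The full pipeline run twice with one fixed seed on the smoke cohort.

    Returns (results of first run, hashes of both bundles, elapsed seconds of
    the first run). Shared session-wide: the double run is the expensive part
    of the suite.
    """
    cfg = RunConfig(seed=17)
    out1 = tmp_path_factory.mktemp("bundle1")
    out2 = tmp_path_factory.mktemp("bundle2")
    t0 = time.time()
    results = run_pipeline(cfg, out1)
    elapsed = time.time() - t0
    run_pipeline(cfg, out2)
    return results, (_bundle_hashes(out1), _bundle_hashes(out2)), elapsed


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
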