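import shutil
import subprocess
from pathlib import Path

import numpy as np
import pytest

from qfmeta.data import ZeroPolicy, summarize_studies, write_studies
from qfmeta.fixtures import make_fixture

HERE = Path(__file__).parent


@pytest.fixture(scope="session")
def stead_like_studies():
    """Synthetic 17-trial dataset shaped like a large sparse-event review."""
    return make_fixture("stead_like", seed=42)


@pytest.fixture(scope="session")
def sparse_studies():
    """Small trials with low event probabilities; contains zero cells."""
    return make_fixture("sparse", seed=7)


@pytest.fixture(scope="session")
def het_summaries(stead_like_studies):
    """Summaries of the 17-trial fixture under the 'always' policy."""
    return summarize_studies(stead_like_studies, ZeroPolicy.ALWAYS)


def random_summaries(rng, k=6, n_range=(30, 200), p_range=(0.1, 0.5)):
    """Random non-degenerate summaries for property tests."""
    from qfmeta.simulate import simulate_study

    studies = []
    while len(studies) < k:
        n = int(rng.integers(*n_range))
        s = simulate_study(2 * (n // 2), 0.5, float(rng.uniform(*p_range)),
                           float(rng.normal(0.3, 0.5)), rng, id=str(len(studies)))
        if not (s.double_zero or s.double_n):
            studies.append(s)
    return summarize_studies(studies, ZeroPolicy.ALWAYS)


@pytest.fixture(scope="session")
def metafor(tmp_path_factory, stead_like_studies, sparse_studies):
    """metafor reference values for both fixtures and both 0.5 policies.

    Returns {(fixture_name, policy): {estimator: value}}.
    """
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    tmp = tmp_path_factory.mktemp("oracle")
    out = {}
    for name, studies in [("stead_like", stead_like_studies), ("sparse", sparse_studies)]:
        csv = tmp / f"{name}.csv"
        write_studies(studies, csv)
        for policy in ("only", "always"):
            proc = subprocess.run(
                ["Rscript", str(HERE / "metafor_oracle.R"), str(csv), policy],
                capture_output=True, text=True, timeout=300,
            )
            assert proc.returncode == 0, proc.stderr
            vals = {}
            for line in proc.stdout.strip().splitlines():
                key, _, val = line.partition("=")
                vals[key.strip()] = float(val)
            out[(name, policy)] = vals
    return out
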