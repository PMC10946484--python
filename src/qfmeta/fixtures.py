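"""Deterministic synthetic datasets mimicking common meta-analytic shapes.

These generators produce *synthetic* 2x2 tables for tests, examples and
benchmarking; none of them reproduces any published dataset.  The
``stead_like`` profile emulates the shape of a large smoking-cessation
review: K = 17 mostly balanced trials with total sizes between roughly 180
and 3100 and low event probabilities (0.04-0.06).
"""

from __future__ import annotations

import zlib

import numpy as np

from .data import Study2x2, write_studies
from .simulate import simulate_study

__all__ = ["PROFILES", "make_fixture"]


def _stead_like(rng: np.random.Generator) -> list[Study2x2]:
    k = 17
    # log-uniform totals in [182, 3128]; two trials get unbalanced arms
    totals = np.exp(rng.uniform(np.log(182), np.log(3128), size=k)).astype(int)
    totals = np.clip(totals, 182, 3128)
    theta = rng.normal(0.6, 0.25, size=k)  # modest benefit, some heterogeneity
    p_c = rng.uniform(0.035, 0.055, size=k)
    studies = []
    for i in range(k):
        f = 0.5 if i >= 2 else 0.35  # first two: more subjects in treatment
        s = simulate_study(int(totals[i]), f, float(p_c[i]), float(theta[i]),
                           rng, id=f"S{i + 1:02d}")
        while s.double_zero or s.double_n:  # keep the fixture non-degenerate
            s = simulate_study(int(totals[i]), f, float(p_c[i]), float(theta[i]),
                               rng, id=f"S{i + 1:02d}")
        studies.append(s)
    return studies


def _sparse(rng: np.random.Generator) -> list[Study2x2]:
    k = 8
    studies = []
    for i in range(k):
        n = int(rng.integers(20, 41))
        s = simulate_study(n, 0.5, 0.05, 0.3, rng, id=f"S{i + 1:02d}")
        studies.append(s)
    if not any(min(s.cells) == 0 for s in studies):
        # force one zero cell deterministically
        s0 = studies[0]
        studies[0] = Study2x2(x_t=s0.x_t, n_t=s0.n_t, x_c=0, n_c=s0.n_c, id=s0.id)
    return studies


def _balanced_small(rng: np.random.Generator) -> list[Study2x2]:
    thetas = rng.normal(0.5, np.sqrt(0.1), size=5)
    return [
        simulate_study(40, 0.5, 0.3, float(t), rng, id=f"S{i + 1:02d}")
        for i, t in enumerate(thetas)
    ]


PROFILES = {
    "stead_like": _stead_like,
    "sparse": _sparse,
    "balanced_small": _balanced_small,
}


def make_fixture(profile: str, seed: int = 0, path=None) -> list[Study2x2]:
    """Generate a named synthetic dataset; optionally write it as CSV."""
    try:
        gen = PROFILES[profile]
    except KeyError:
        raise KeyError(
            f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
        ) from None
    key = zlib.crc32(profile.encode()) % 2**31  # stable across processes
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
    studies = gen(rng)
    if path is not None:
        write_studies(studies, path)
    return studies
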