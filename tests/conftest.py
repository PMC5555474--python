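"""Shared fixtures: one synthetic assembly and one pipeline run per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rdnarip import mining, synthetic
from rdnarip.pipeline import RunConfig, run_pipeline

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def exact_mutate(seq: str, n_subs: int, seed: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions (uniform alt base)."""
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in rng.choice(len(seq), size=n_subs, replace=False):
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[rng.integers(3)]
    return "".join(out)


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-5.0, extend=-1.0) -> float:
    """Exhaustive affine-gap global alignment score (Gotoh DP).

    Gap of length L costs open + (L-1)*extend, matching the package's
    aligner convention. Independent oracle for short strings.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a residue vs gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend, X[i, j - 1] + open_)
    return float(max(M[n, m], X[n, m], Y[n, m]))


@pytest.fixture(scope="session")
def template():
    return synthetic.generate_reference_unit(rng_seed=1)


@pytest.fixture(scope="session")
def assembly(template):
    """Default-condition synthetic assembly: 10 paralogs, 80% pseudogenes."""
    params = synthetic.RipParams(n_paralogs=10, pseudogene_fraction=0.8, seed=7)
    contigs, truth = synthetic.build_synthetic_assembly(template, params)
    return contigs, truth


@pytest.fixture(scope="session")
def mined(template, assembly):
    contigs, truth = assembly
    hits = mining.iterative_search(contigs, template.sequence)
    return contigs, truth, hits


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    cfg = RunConfig(seed=3, outdir=str(tmp_path_factory.mktemp("pipe")), n_bootstrap=30)
    return run_pipeline(cfg)
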