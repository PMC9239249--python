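"""Shared fixtures. The expensive end-to-end runs are session-scoped and
reused across unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from microvinet.pipeline import (
    annotate_and_curate, build_hallmark_profiles, classify_genomes,
)
from microvinet.simulate import (
    make_seed_msas, simulate_taxonomy, strip_annotations,
)


@pytest.fixture(scope="session")
def small_planted():
    """3 families x 2 genera x 2 genomes with truth annotations."""
    genomes, truth = simulate_taxonomy(
        n_families=3, genera_per_family=2, genomes_per_genus=2, seed=7
    )
    return genomes, truth


@pytest.fixture(scope="session")
def small_profiles(small_planted):
    _, truth = small_planted
    return build_hallmark_profiles(make_seed_msas(truth), seed=7)


@pytest.fixture(scope="session")
def planted_full():
    """The default study conditions: 5 families x 3 genera x 4 genomes,
    seed 42, full raw-contig path (ORF calling, profile labeling, curation,
    classification)."""
    genomes, truth = simulate_taxonomy(seed=42)
    profiles = build_hallmark_profiles(make_seed_msas(truth), seed=42)
    report = annotate_and_curate(strip_annotations(genomes), profiles)
    model = classify_genomes(report.curated)
    return {
        "genomes": genomes,
        "truth": truth,
        "profiles": profiles,
        "report": report,
        "model": model,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
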