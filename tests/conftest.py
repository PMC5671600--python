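import numpy as np
import pytest
from hypothesis import settings

import sagbin as sb
from sagbin.mlp_classifier import Hyperparameters, segments_to_xy, train_mlp
from sagbin.trimer_features import clip_segments

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_bench():
    """3 populations (one decoy), 100-kb genomes, 2,000 reads; quick but
    statistically meaningful."""
    return sb.synthetic_community.benchmark_community(
        seed=11, n_populations=3, n_decoys=1, genome_length=100_000,
        n_reads=2_000, n_contigs=4,
    )


@pytest.fixture(scope="session")
def separable_setup():
    """Two well-separated populations (JSD >= 0.1 bits), 100 labeled 2-kb
    segments each, plus a trained model. Shared by classifier tests."""
    seed = 7
    transitions = sb.design_populations(2, 0.1, seed=seed)
    genomes = [
        sb.generate_genome(
            sb.PopulationSpec(
                label=f"pop{i}", genome_length=210_000,
                transition=t, seed=seed + 1 + i,
            )
        )
        for i, t in enumerate(transitions)
    ]
    segments = []
    for i, g in enumerate(genomes):
        segments.extend(clip_segments([g], labels=f"pop{i}")[:100])
    X, y = segments_to_xy(segments)
    model = train_mlp(X, y, Hyperparameters(seed=seed))
    return {
        "transitions": transitions,
        "genomes": genomes,
        "segments": segments,
        "X": X,
        "y": y,
        "model": model,
        "seed": seed,
    }
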