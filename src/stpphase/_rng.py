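"""Seed plumbing: everything funnels through numpy SeedSequence spawning."""

import numpy as np

RngLike = "np.random.Generator | int | np.random.SeedSequence"


def as_seedseq(rng) -> np.random.SeedSequence:
    """Coerce a Generator / SeedSequence / int seed to a SeedSequence."""
    if isinstance(rng, np.random.Generator):
        return rng.bit_generator.seed_seq
    if isinstance(rng, np.random.SeedSequence):
        return rng
    return np.random.SeedSequence(rng)


def generator_from(seq: np.random.SeedSequence) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seq))
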