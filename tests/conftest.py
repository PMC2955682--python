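import numpy as np
import pytest

import codonscan as cs


@pytest.fixture(scope="session")
def trained_matrix() -> cs.CodonSubstitutionMatrix:
    """Log-odds matrix from a synonymous-biased synthetic training set.

    2000 alignments x 260 codons mimics the scale of an orthologous CDS
    training corpus closely enough for stable cell frequencies.
    """
    rng = np.random.default_rng(1)
    training = cs.build_training_set(cs.CodingModel(n_codons=260), 2000, rng)
    return cs.lod_from_counts(cs.count_codon_pairs(training), pseudocount=0.5)


@pytest.fixture(scope="session")
def calibration(trained_matrix) -> cs.CalibrationResult:
    """Karlin-Altschul constants fitted on 100 null sequences of 10 kb."""
    model = cs.NullModel(seq_length=10_000, n_sequences=100, seed=11)
    return cs.calibrate(model, trained_matrix)
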