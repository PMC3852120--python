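import numpy as np
import pandas as pd
import pytest

from genohap.popgen import analyze_replicate, generate_pool, sample_case_control, select_causal

NULL_STUDY_SEED = 20130821


@pytest.fixture(scope="session")
def null_study() -> pd.DataFrame:
    """Scaled null simulation study: 1000 case-control replicates (500/500)
    from fresh 40,000-chromosome pools, no causal variants, 200 permutations
    per replicate; returns the four tests' p-values per replicate."""
    rows = []
    for r in range(1000):
        ss = np.random.SeedSequence((NULL_STUDY_SEED, r))
        s1, s2, s3 = (int(x) for x in ss.generate_state(3) % (2**31 - 1) + 1)
        pool = generate_pool(seed=s1)
        model = select_causal(pool, "genotype", "null", 0.0, seed=s2)
        sample = sample_case_control(pool, model, seed=s2)
        rows.append(analyze_replicate(sample, n_permutations=200, seed=s3))
    return pd.DataFrame(rows)
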