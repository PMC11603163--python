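import pytest
from hypothesis import settings

import exconsv as x

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """Simulated families under the standard recovery conditions, seed 1."""
    return x.simulate_families(x.default_sim_config(seed=1))


@pytest.fixture(scope="session")
def default_profiles(default_bundle):
    aln, _, _ = default_bundle
    cmap = x.build_column_map(aln)
    profiles = x.profiles_for_groups(aln, cmap, ("D1", "B1", "E1"))
    return cmap, profiles


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path
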