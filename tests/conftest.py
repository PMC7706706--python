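import numpy as np
import pytest

from spo11map import GenomeAssembly, NormState, SignalMap, load_default_assembly
from spo11map.simulate import toy_assembly


@pytest.fixture(scope="session")
def saccer2():
    return load_default_assembly()


@pytest.fixture(scope="session")
def toy():
    return toy_assembly()


@pytest.fixture(scope="session")
def mini():
    """One 100-kb chromosome with a centromere at 50 kb; no rDNA."""
    return GenomeAssembly(("chrT",), {"chrT": 100_000}, {"chrT": 50_000})


def make_map(assembly, arrays, state=NormState.RAW):
    """SignalMap from {chrom: values-or-(pos, val) pairs}."""
    data = {}
    for chrom, spec in arrays.items():
        arr = np.zeros(assembly.length_of(chrom))
        if isinstance(spec, dict):
            for pos, val in spec.items():
                arr[pos - 1] = val
        else:
            vals = np.asarray(spec, dtype=float)
            arr[: vals.size] = vals
        data[chrom] = arr
    return SignalMap(assembly, data, state)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
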