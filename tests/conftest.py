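import numpy as np
import pandas as pd
import pytest

from riqtl.io_formats import GenotypeMatrix
from riqtl.simulate import ChromosomeSpec, ExpressionSpec, SimConfig, make_fixture


def toy_genotypes(calls, chrom="1", spacing_cM=10.0, strains=None):
    """GenotypeMatrix from a (markers x strains) list of code strings."""
    calls = np.array(calls, dtype="<U1")
    n_mark, n_str = calls.shape
    strains = strains or [f"S{i}" for i in range(n_str)]
    markers = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(n_mark)],
        "chromosome": chrom,
        "cM": np.arange(n_mark) * spacing_cM,
        "Mb": np.arange(n_mark) * spacing_cM * 2.0,
    })
    return GenotypeMatrix(strains, markers, calls)


def trait_frame(values, strains=None, se=None, n=None):
    strains = strains or [f"S{i}" for i in range(len(values))]
    return pd.DataFrame(
        {"value": np.asarray(values, float),
         "se": np.asarray(se, float) if se is not None else np.nan,
         "n": np.asarray(n, float) if n is not None else np.nan},
        index=pd.Index(strains, name="strain"))


@pytest.fixture(scope="session")
def demo_fixture():
    """Default-condition panel used by the expression-side tests."""
    return make_fixture(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_mapping_config():
    """Reduced genome for mapping-statistics tests that loop over panels."""
    return SimConfig(
        n_strains=75,
        chromosomes=[ChromosomeSpec(str(c), 60.0, 4.0) for c in range(1, 6)],
        qtl=[], var_strain=1.0, var_within=0.01,
        replicates_per_strain=(1, 1), field_level=False, age_slope=0.0,
        expression=ExpressionSpec(n_genes=10, n_interval_genes=2, n_cis_genes=2,
                                  n_module_genes=2),
        interval=("1", 0.0, 10.0), seed=0)
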