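import numpy as np
import pandas as pd
import pytest

from seromir.quantify import Precursor, ReadAlignment


@pytest.fixture
def precursor():
    """One '+'-strand hairpin: span [1000, 1120), -5p [1015, 1039), -3p [1081, 1105)."""
    return Precursor(
        precursor_id="mir-x", chrom="chr1", start=1000, end=1120, strand="+",
        mature5p=(1015, 1039), mature3p=(1081, 1105),
    )


@pytest.fixture
def annotation(precursor):
    minus = Precursor(
        precursor_id="mir-y", chrom="chr1", start=2000, end=2120, strand="-",
        mature5p=(2081, 2105), mature3p=(2015, 2039),
    )
    return [precursor, minus]


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 500, size=(6, 5))
    return pd.DataFrame(
        counts,
        index=pd.Index([f"mir-{i}" for i in range(6)], name="feature"),
        columns=[f"s{i}" for i in range(5)],
    )
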