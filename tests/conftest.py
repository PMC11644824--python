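import io

import pandas as pd
import pytest

from triterplib import (
    attach_theoretical_spectra,
    load_reference_library,
    load_reference_queries,
)
from triterplib.library import packaged_path


@pytest.fixture(scope="session")
def reference_library():
    """The packaged 43-compound triterpenoid library with curated spectra."""
    return load_reference_library()


@pytest.fixture(scope="session")
def theo_library(reference_library):
    """Reference library where spectrum-less records carry deterministic
    theoretical product-ion spectra (for simulation/recovery experiments)."""
    return attach_theoretical_spectra(reference_library)


@pytest.fixture(scope="session")
def compound_frame():
    """The transcribed compound table as a DataFrame (printed values intact)."""
    return pd.read_csv(io.StringIO(packaged_path("reference_compounds.csv").read_text()), comment="#")


@pytest.fixture(scope="session")
def reference_queries():
    return load_reference_queries()
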