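import warnings

import pytest

from litsumm.context import Context
from litsumm.fixtures import small_context

warnings.filterwarnings("ignore", module="umap")
warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture(scope="session")
def base_context() -> Context:
    """A small fits-budget context shared by audit/pipeline tests."""
    return small_context(seed=1)
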