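import pytest

import photoclamp as pc


@pytest.fixture(scope="session")
def consensus():
    """Factory: cell type -> (consensus params, dark operating point at the
    representative dark current)."""

    def get(cell_type):
        params = pc.consensus_params(cell_type)
        dark = pc.dark_operating_point(params, pc.default_dark_current(cell_type))
        return params, dark

    return get


@pytest.fixture(scope="session")
def linear_filter_cache(consensus):
    """Session-wide cache of fitted linear filters: fitting takes seconds
    per (cell type, mean) so several tests share the result."""
    cache = {}

    def get(cell_type, mean_level, seed=11):
        key = (cell_type, mean_level, seed)
        if key not in cache:
            params, dark = consensus(cell_type)
            cache[key] = pc.fit_linear_model(params, dark, mean_level, seed=seed)
        return cache[key]

    return get
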