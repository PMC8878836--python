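import numpy as np
import pytest

from dgcmeta import EffectSize


def make_effects(values, variances, tag="hedges_g", orders=None):
    """Build a homogeneous effect-size list for pooling tests."""
    orders = orders or ["Orthoptera"] * len(values)
    return [
        EffectSize(value=float(y), variance=float(v), study_id=f"s{i:03d}",
                   family_tag=tag, subgroup=o,
                   taxonomy_path=(o, f"{o}_fam", f"{o}_sp{i}"))
        for i, (y, v, o) in enumerate(zip(values, variances, orders))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def tiny_effects():
    """Five-effect fixture used for frozen cross-package oracle values."""
    return make_effects([-3.0, -4.0, -2.0, -3.5, -2.5],
                        [0.5, 0.4, 0.6, 0.3, 0.45])
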