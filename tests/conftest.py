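import numpy as np
import pytest

from repacid.reparam import BranchConvBN, RepACIDTrainBlock, RepVGGTrainBlock


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_branch(rng, cout, cin, shape):
    """A BranchConvBN with random kernel and non-trivial BN statistics."""
    return BranchConvBN(
        kernel=rng.normal(size=(cout, cin) + shape),
        bn_gamma=rng.uniform(0.5, 2.0, cout),
        bn_beta=rng.normal(size=cout),
        bn_mean=rng.normal(size=cout),
        bn_var=rng.uniform(0.1, 2.0, cout),
        bn_eps=1e-3,
    )


def randomize_block(block, rng):
    """Give a training block random weights and random (valid) BN stats."""
    for p in block.params().values():
        p[...] = rng.normal(0, 0.5, p.shape)
    for name, b in block.buffers().items():
        if name.endswith("running_mean"):
            b[...] = rng.normal(0, 0.5, b.shape)
        else:
            b[...] = rng.uniform(0.2, 2.0, b.shape)
    return block


def make_block(kind, cin, cout, stride, rng, activation="silu"):
    cls = RepACIDTrainBlock if kind == "repacid" else RepVGGTrainBlock
    return randomize_block(cls(cin, cout, stride, activation=activation,
                               rng=rng), rng)
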