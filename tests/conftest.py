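import numpy as np
import pytest

import chanpid as cp

#: reduced solver effort for the randomized property suites (documented in
#: docs/methods.md); the worked examples in the acceptance tests use the
#: package defaults
LIGHT_OPTS = cp.SolverOptions(
    seed=0,
    restarts=12,
    sampled_restarts=2,
    n_dirichlet=40,
    max_kept_constraints=120,
    slsqp_maxiter=80,
)


@pytest.fixture(scope="session")
def and_joint():
    return cp.gate_joint("AND")


@pytest.fixture(scope="session")
def copy_joint():
    return cp.gate_joint("COPY")


@pytest.fixture(scope="session")
def ce1_pair():
    return cp.counterexample1()


@pytest.fixture(scope="session")
def ds_pair():
    return cp.ds_example()


@pytest.fixture(scope="session")
def p_334():
    return cp.SimplexPoint.from_weights([0.3, 0.3, 0.4])


@pytest.fixture(scope="session")
def p_46():
    return cp.SimplexPoint.from_weights([0.4, 0.6])


def joint_with_tuple_source(joint):
    """Rewrite a two-source joint (t, y1, y2) as (t, y1, (y1, y2)): the
    second source becomes the pair, so source 1 is nested inside source 2."""
    records = [
        ((o[0], o[1], (o[1], o[2])), p) for o, p in joint.prob.items()
    ]
    return cp.joint_from_table(records, variable_names=("t", "y1", "y12"))


def source_channels(joint):
    p_t, _ = cp.channel_from_joint(joint, 1)
    return p_t, [cp.channel_from_joint(joint, i)[1] for i in range(1, joint.n_sources + 1)]


def random_copy_joint(seed, sizes=(2, 2)):
    """Copy target T=(Y1,Y2) with independent sources and random marginals."""
    rng = np.random.default_rng(seed)
    m1 = rng.dirichlet(np.ones(sizes[0]))
    m2 = rng.dirichlet(np.ones(sizes[1]))
    records = [
        (((a, b), a, b), float(m1[a] * m2[b]))
        for a in range(sizes[0])
        for b in range(sizes[1])
    ]
    return cp.joint_from_table(records)
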