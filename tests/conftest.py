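import numpy as np
import pytest

from phenotracer import make_hysteresis_scenario


@pytest.fixture(scope="session")
def scenario():
    return make_hysteresis_scenario(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_fraction_series(rng, K, T, noise=0.01):
    """A well-conditioned random fraction series with all states occupied."""
    P = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi = rng.dirichlet(np.ones(K) * 5.0)
    rows = [pi]
    for _ in range(T - 1):
        rows.append(rows[-1] @ P)
    fr = np.array(rows)
    if noise:
        fr = np.abs(fr + rng.normal(0, noise, fr.shape))
        fr /= fr.sum(axis=1, keepdims=True)
    return fr


def well_conditioned_fractions(rng, K, T, max_cond=500.0):
    """Fraction series whose predictor rows are far from collinear.

    Propagating a Markov chain converges toward its stationary
    distribution, which makes F^T F nearly singular and the QP optimum
    degenerate along the null direction; solver-equivalence checks need a
    unique, well-conditioned optimum, so rows here are i.i.d. Dirichlet,
    resampled until the predictor Gram matrix is well conditioned.
    """
    while True:
        fr = rng.dirichlet(np.ones(K) * 1.5, size=T)
        if np.linalg.cond(fr[:-1].T @ fr[:-1]) < max_cond:
            return fr


def slsqp_transition_fit(fractions, lam):
    """Independent general-purpose QP solve of the transition objective.

    Uses scipy's SLSQP on the flattened K*K problem with explicit row-sum
    equality constraints and box bounds — a fully separate optimization
    route from the package's projected-gradient solver.
    """
    from scipy.optimize import minimize

    F, G = fractions[:-1], fractions[1:]
    K = fractions.shape[1]
    mask = np.ones((K, K)) - np.eye(K)

    def obj(x):
        P = x.reshape(K, K)
        r = G - F @ P
        return float((r * r).sum() + lam * (mask * P).sum())

    def grad(x):
        P = x.reshape(K, K)
        return (2.0 * F.T @ (F @ P - G) + lam * mask).ravel()

    constraints = [
        {
            "type": "eq",
            "fun": (lambda x, j=j: x.reshape(K, K)[j].sum() - 1.0),
            "jac": (
                lambda x, j=j: np.eye(K * K)[j * K : (j + 1) * K].sum(axis=0)
            ),
        }
        for j in range(K)
    ]
    res = minimize(
        obj,
        np.full(K * K, 1.0 / K),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * (K * K),
        constraints=constraints,
        options={"maxiter": 2000, "ftol": 1e-16},
    )
    return res.x.reshape(K, K)
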