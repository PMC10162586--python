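"""Synthetic joint distributions and observation samplers.

These generators provide the example systems used throughout the tests
and documentation: small symmetric noisy channels whose information
quantities have closed forms, a large near-uniform joint with grouped
predictive profiles that showcases the deterministic bottleneck, fully
random joints, and a seeded sampler that turns any joint into paired
observation sequences.  Identical parameters and seed always produce
identical output.
"""

from __future__ import annotations

import numpy as np

from .distributions import Alphabet, JointPMF


def binary_symmetric_joint(flip_prob: float) -> JointPMF:
    """Uniform binary X through a binary symmetric channel.

    I(X:Y) = 1 - H2(flip_prob) bits, where H2 is the binary entropy.
    """
    if not 0.0 <= flip_prob <= 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5]")
    p = flip_prob
    mat = 0.5 * np.array([[1 - p, p], [p, 1 - p]])
    return JointPMF(mat, Alphabet((0, 1)), Alphabet((0, 1)))


def k_symbol_noisy_joint(k: int, flip_prob: float) -> JointPMF:
    """Uniform k-ary X through a symmetric channel.

    The channel keeps the symbol with probability 1 - flip_prob and
    spreads flip_prob uniformly over the other k - 1 symbols, so
    I(X:Y) = log2 k - H(1 - flip_prob, flip_prob/(k-1), ...).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0.0 <= flip_prob <= (k - 1) / k:
        raise ValueError(f"flip_prob must lie in [0, {(k - 1) / k}]")
    channel = np.full((k, k), flip_prob / (k - 1))
    np.fill_diagonal(channel, 1.0 - flip_prob)
    mat = channel / k
    symbols = Alphabet(tuple(range(k)))
    return JointPMF(mat, symbols, Alphabet(tuple(range(k))))


def near_uniform_dib_joint(
    n_x: int = 128,
    n_y: int = 32,
    concentration: float = 0.2,
    seed: int = 0,
) -> JointPMF:
    """Large joint with near-uniform p(x) and grouped predictive profiles.

    p(x) is uniform up to a small seeded jitter (each entry within
    0.25/n_x of 1/n_x).  The rows p(y|x) are built from a handful of
    prototype profiles drawn from a symmetric Dirichlet with the given
    concentration; x values assigned to the same prototype share similar
    predictive profiles, giving the deterministic bottleneck cluster
    structure to exploit.  Each row mixes in 10% fresh Dirichlet(1)
    noise, which keeps full support.  Deterministic in the seed.
    """
    if n_x < n_y or n_y < 2:
        raise ValueError("need n_x >= n_y >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_x, n_y]))

    jitter = rng.uniform(-0.1, 0.1, size=n_x)
    px = (1.0 + jitter) / n_x
    px = px / px.sum()

    n_groups = max(2, n_y // 4)
    prototypes = rng.dirichlet(np.full(n_y, concentration), size=n_groups)
    noise = rng.dirichlet(np.ones(n_y), size=n_x)
    groups = np.arange(n_x) % n_groups
    py_given_x = 0.9 * prototypes[groups] + 0.1 * noise

    mat = px[:, None] * py_given_x
    mat = mat / mat.sum()
    return JointPMF(mat, Alphabet(tuple(range(n_x))), Alphabet(tuple(range(n_y))))


def random_joint(n_x: int, n_y: int, seed: int = 0) -> JointPMF:
    """Fully random joint: positive entries, normalized (flat Dirichlet)."""
    if n_x < 1 or n_y < 1:
        raise ValueError("need n_x, n_y >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_x, n_y, 1]))
    mat = rng.exponential(size=(n_x, n_y))
    mat = mat / mat.sum()
    return JointPMF(mat, Alphabet(tuple(range(n_x))), Alphabet(tuple(range(n_y))))


def sample_observations(joint: JointPMF, n: int, seed: int = 0):
    """n i.i.d. paired draws (x_obs, y_obs) from a joint pmf, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n]))
    flat = joint.matrix.ravel()
    idx = rng.choice(flat.size, size=n, p=flat)
    xi, yi = np.unravel_index(idx, joint.matrix.shape)
    x_obs = [joint.x_alphabet[i] for i in xi]
    y_obs = [joint.y_alphabet[i] for i in yi]
    return x_obs, y_obs
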