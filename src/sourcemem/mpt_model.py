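"""The dual-process source-item multinomial processing tree (MPT).

Six probabilities govern the three response categories in each of the three
trial trees (UP, DOWN, NEW):

* ``S_up``, ``S_down`` — recollection: object *and* position retrieved
  jointly, forcing the correct old+source answer.
* ``I_up``, ``I_down`` — familiarity: when recollection fails, the item may
  still be recognised as old without its position; the source answer is then
  guessed.
* ``o`` — guessing that an unrecognised item is old.
* ``g`` — guessing "up" whenever a source answer must be guessed.  One shared
  ``g`` applies both after successful familiarity and after an uninformed
  "old" guess: this is the conventional, identifiable source-item topology
  (a guess is required in both situations, and the data cannot separate two
  guessing rates in this design).

Category probabilities, e.g. for the UP tree::

    P(old_up)   = S_up + (1-S_up) I_up g + (1-S_up)(1-I_up) o g
    P(old_down) = (1-S_up) I_up (1-g) + (1-S_up)(1-I_up) o (1-g)
    P(new)      = (1-S_up)(1-I_up)(1-o)

The DOWN tree mirrors this with recollection leading to old_down; the NEW
tree has no memory branches: ``P(old_up) = o g``, ``P(old_down) = o (1-g)``,
``P(new) = 1 - o``.

The model is just-identified (6 free parameters, 6 free category
probabilities), so the maximum-likelihood fit matches the closed-form moment
estimator and G-squared at the MLE is zero up to numerical tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .task_data import FrequencyTable

__all__ = [
    "PARAM_NAMES",
    "MPTParams",
    "category_probabilities",
    "category_probabilities_array",
    "log_likelihood",
    "moment_estimator",
    "MomentEstimate",
    "fit_mle",
    "MLEFit",
    "g_squared",
]

PARAM_NAMES = ("S_up", "S_down", "I_up", "I_down", "o", "g")


@dataclass(frozen=True)
class MPTParams:
    """The six branch probabilities; each in [0, 1], no sum constraint."""

    s_up: float
    s_down: float
    i_up: float
    i_down: float
    o: float
    g: float

    def __post_init__(self):
        for name, v in zip(PARAM_NAMES, self.as_array()):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_up, self.s_down, self.i_up, self.i_down,
                         self.o, self.g], dtype=float)

    @classmethod
    def from_array(cls, a) -> "MPTParams":
        a = np.asarray(a, dtype=float)
        return cls(*a)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.as_array()))


def category_probabilities_array(theta: np.ndarray) -> np.ndarray:
    """Vectorised category probabilities.

    ``theta`` has shape (..., 6) ordered (S_up, S_down, I_up, I_down, o, g);
    returns shape (..., 3, 3) with rows (UP, DOWN, NEW) and columns
    (old_up, old_down, new).  Each row sums to 1 exactly by construction.
    """
    theta = np.asarray(theta, dtype=float)
    s_up, s_down, i_up, i_down, o, g = np.moveaxis(theta, -1, 0)
    out = np.empty(theta.shape[:-1] + (3, 3), dtype=float)
    # UP tree
    out[..., 0, 0] = s_up + (1 - s_up) * i_up * g + (1 - s_up) * (1 - i_up) * o * g
    out[..., 0, 1] = (1 - s_up) * i_up * (1 - g) + (1 - s_up) * (1 - i_up) * o * (1 - g)
    out[..., 0, 2] = (1 - s_up) * (1 - i_up) * (1 - o)
    # DOWN tree: recollection yields old_down; g still P(guess "up")
    out[..., 1, 0] = (1 - s_down) * i_down * g + (1 - s_down) * (1 - i_down) * o * g
    out[..., 1, 1] = s_down + (1 - s_down) * i_down * (1 - g) + (1 - s_down) * (1 - i_down) * o * (1 - g)
    out[..., 1, 2] = (1 - s_down) * (1 - i_down) * (1 - o)
    # NEW tree
    out[..., 2, 0] = o * g
    out[..., 2, 1] = o * (1 - g)
    out[..., 2, 2] = 1 - o
    return out


def category_probabilities(params: MPTParams) -> np.ndarray:
    """3x3 category probabilities for a single parameter set."""
    return category_probabilities_array(params.as_array())


def log_likelihood(freq: FrequencyTable, params: MPTParams) -> float:
    """Multinomial log-likelihood of the table, summed over the three trees.

    Returns -inf when a zero-probability category holds a positive count.
    The multinomial coefficient (constant in the parameters) is omitted.
    """
    probs = category_probabilities(params)
    counts = freq.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(probs), 0.0)
    if np.isnan(terms).any() or np.isneginf(terms).any():
        return -np.inf
    return float(terms.sum())


@dataclass(frozen=True)
class MomentEstimate:
    params: MPTParams
    clipped: bool  # True if any raw estimate fell outside [0, 1]


class EstimationError(ValueError):
    pass


def moment_estimator(freq: FrequencyTable) -> MomentEstimate:
    """Closed-form inversion of the just-identified tree.

    The NEW tree gives ``o`` and ``g`` directly; each old tree then yields
    (1-S)(1-I) from its "new" cell and (1-S)I from its off-position cell,
    from which S and I follow.  Raw estimates outside [0, 1] are clipped and
    flagged.
    """
    c = freq.counts.astype(float)
    n_new = c[2].sum()
    if n_new == 0:
        raise EstimationError("NEW tree has no observations")
    o = 1.0 - c[2, 2] / n_new
    old_guesses = c[2, 0] + c[2, 1]
    if old_guesses == 0:
        raise EstimationError("no old-guesses in NEW tree: g undefined (cell new/old_up + new/old_down)")
    g = c[2, 0] / old_guesses
    if o >= 1.0 - 1e-12:
        raise EstimationError("o = 1: cell NEW/new is empty, old trees not invertible")

    clipped = False

    def invert_old_tree(row: np.ndarray, off_col: int, guess_weight: float) -> tuple[float, float]:
        # off_col/guess_weight: the off-position cell and its source-guess
        # probability — old_down with weight (1-g) for the UP tree, old_up
        # with weight g for the DOWN tree.
        nonlocal clipped
        n = row.sum()
        if n == 0:
            raise EstimationError("old tree has no observations")
        if guess_weight <= 1e-12:
            raise EstimationError("source-guess weight is zero: off-position cell uninformative")
        p_new = row[2] / n
        p_off = row[off_col] / n
        a = p_new / (1.0 - o)            # (1-S)(1-I)
        b = p_off / guess_weight - a * o  # (1-S)I
        s = 1.0 - a - b
        i = b / (a + b) if (a + b) > 1e-12 else 1.0
        for v in (s, i):
            if v < 0.0 or v > 1.0:
                clipped = True
        return float(np.clip(s, 0, 1)), float(np.clip(i, 0, 1))

    s_up, i_up = invert_old_tree(c[0], 1, 1.0 - g)
    s_down, i_down = invert_old_tree(c[1], 0, g)
    raw = np.array([s_up, s_down, i_up, i_down, o, g])
    if ((raw < 0) | (raw > 1)).any():
        clipped = True
    params = MPTParams.from_array(np.clip(raw, 0.0, 1.0))
    return MomentEstimate(params, clipped)


@dataclass(frozen=True)
class MLEFit:
    params: MPTParams
    log_likelihood: float
    g_squared: float
    n_starts: int
    seed: int
    boundary: tuple[str, ...]  # parameters at the [0,1] boundary
    converged: bool


_LOGIT_CLIP = 1e-9


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def fit_mle(freq: FrequencyTable, init: MPTParams | None = None,
            n_starts: int = 10, seed: int = 0) -> MLEFit:
    """Maximum-likelihood fit by bounded quasi-Newton search on the logit scale.

    Multi-start (the moment estimate, when available, plus random draws);
    the best optimum by log-likelihood is retained, ties broken by the
    smaller parameter L2 norm.  On interior optima of non-degenerate tables
    this coincides with :func:`moment_estimator` (just-identified model).
    """
    counts = freq.counts.astype(float)

    def neg_ll(x: np.ndarray) -> float:
        probs = category_probabilities_array(_expit(x))
        probs = np.clip(probs, 1e-300, 1.0)
        return -float((counts * np.log(probs)).sum())

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(_logit(init.as_array()))
    else:
        try:
            starts.append(_logit(moment_estimator(freq).params.as_array()))
        except EstimationError:
            pass
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(rng.normal(0.0, 1.5, size=6))

    best: tuple[float, float, np.ndarray] | None = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B")
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or res.success
        theta = _expit(res.x)
        key = (res.fun, float(np.linalg.norm(theta)))
        if best is None or key < (best[0], best[1]):
            best = (res.fun, key[1], theta)
    if best is None or not any_success:
        raise RuntimeError(f"MLE failed to converge in {n_starts} starts (seed {seed})")

    theta = best[2]
    boundary = tuple(name for name, v in zip(PARAM_NAMES, theta)
                     if v < 1e-6 or v > 1 - 1e-6)
    theta = np.clip(theta, 0.0, 1.0)
    params = MPTParams.from_array(theta)
    return MLEFit(
        params=params,
        log_likelihood=log_likelihood(freq, params),
        g_squared=g_squared(freq, params),
        n_starts=len(starts),
        seed=seed,
        boundary=boundary,
        converged=True,
    )


def g_squared(freq: FrequencyTable, params: MPTParams) -> float:
    """Likelihood-ratio fit statistic 2 * sum obs * log(obs / exp), 0*log0 = 0."""
    counts = freq.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    expected = category_probabilities(params) * totals
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, counts * np.log(counts / expected), 0.0)
    if np.isnan(terms).any():
        return float("inf")
    return float(2.0 * terms.sum())
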