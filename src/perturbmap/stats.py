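"""Permutation tests for mean differences, effect sizes, Bonferroni.

Two-sided paired or unpaired permutation (randomization) tests with
10,000 iterations by default; the smallest attainable p is
1/n_iterations (0.0001 at the default), implemented by counting with a
floor of one.  Effect sizes are Cohen's d with a pooled SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PermutationResult", "permutation_test", "bonferroni"]


@dataclass
class PermutationResult:
    p: float
    observed_diff: float
    effect_size: float
    n_iterations: int
    paired: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1.0 / self.n_iterations) - 1e-12 <= self.p <= 1.0:
            raise ValueError("p outside [1/n_iterations, 1]")


def _cohens_d(x: np.ndarray, y: np.ndarray, paired: bool) -> float:
    if paired:
        d = x - y
        s = d.std(ddof=1)
        return float(d.mean() / s) if s > 0 else 0.0
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    diff = x.mean() - y.mean()
    return float(diff / pooled) if pooled > 0 else 0.0


def permutation_test(x, y, paired: bool = False, n_iterations: int = 10000,
                     seed: int | np.random.Generator = 0) -> PermutationResult:
    """Two-sided permutation test for a difference in means.

    Unpaired: group labels are permuted.  Paired: per-pair differences get
    random sign flips.  p = max(#{|null| >= |observed|}, 1)/n_iterations.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if paired and (x.size != y.size or x.size < 2):
        raise ValueError("paired test needs equal lengths >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(x.mean() - y.mean())

    if paired:
        d = x - y
        n = d.size
        null = np.empty(n_iterations)
        chunk = max(1, int(2e7 // max(n, 1)))
        for s0 in range(0, n_iterations, chunk):
            c = min(chunk, n_iterations - s0)
            signs = rng.choice([-1.0, 1.0], size=(c, n))
            null[s0:s0 + c] = (signs * d).mean(axis=1)
    else:
        pooled = np.concatenate([x, y])
        nx, ntot = x.size, pooled.size
        null = np.empty(n_iterations)
        chunk = max(1, int(2e7 // ntot))
        for s0 in range(0, n_iterations, chunk):
            c = min(chunk, n_iterations - s0)
            mat = np.tile(pooled, (c, 1))
            mat = rng.permuted(mat, axis=1)
            mx = mat[:, :nx].mean(axis=1)
            my = mat[:, nx:].mean(axis=1)
            null[s0:s0 + c] = mx - my
    count = int((np.abs(null) >= abs(observed) - 1e-15).sum())
    p = max(count, 1) / n_iterations
    eff = _cohens_d(x, y, paired)
    return PermutationResult(p=float(p), observed_diff=observed,
                             effect_size=eff, n_iterations=n_iterations,
                             paired=paired,
                             seed=None if isinstance(seed, np.random.Generator) else seed)


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05) -> np.ndarray:
    """Family-wise significance decisions: p < alpha/m.

    ``m`` defaults to the number of p-values supplied.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    m_eff = int(m) if m is not None else p.size
    if m_eff < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m_eff
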