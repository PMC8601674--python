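"""Independent reference implementations used as desk-check oracles.

Everything here deliberately avoids the algorithms used by the production
code: reconstruction by explicit least squares on the discrete Fourier
encoding matrix (vs Kaiser-Bessel gridding), the Jonckheere-Terpstra null
by brute-force enumeration of label assignments (vs the dynamic-programming
convolution), and the Wilcoxon null by full 2^n sign enumeration (vs
scipy). They are practical only at toy sizes and exist to catch systematic
errors in the fast paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .acquisition import RadialKSpace

__all__ = [
    "dft_least_squares_reconstruct",
    "conjugate_phase_reconstruct",
    "jt_statistic_naive",
    "jt_exact_p_enumeration",
    "wilcoxon_exact_p_enumeration",
]


def _encoding_matrix(kspace: RadialKSpace, grid_size_px: int) -> np.ndarray:
    n = grid_size_px
    px = kspace.fov_mm / n
    ax = (np.arange(n) - n // 2) * px
    x, y = np.meshgrid(ax, ax, indexing="xy")
    kx, ky = kspace.trajectory.kvectors()
    return np.exp(
        -2j * np.pi * (kx.ravel()[:, None] * x.ravel()[None, :]
                       + ky.ravel()[:, None] * y.ravel()[None, :])
    ) * px**2


def dft_least_squares_reconstruct(
    kspace: RadialKSpace, grid_size_px: int, echo: int = 0, rcond: float = 1e-2
) -> np.ndarray:
    """Least-squares image from the explicit non-uniform DFT encoding matrix.

    Builds A with A[i, p] = exp(-2i pi k_i . x_p) * pixel_area (the same
    continuous-FT convention as the forward model) and solves
    min ||A f - s||_2, truncating singular values below rcond — the
    explicit system is badly conditioned at fine radial sample spacing.
    Only feasible for grids up to ~32^2.
    """
    if grid_size_px > 40:
        raise ValueError("explicit DFT oracle is limited to small grids")
    a = _encoding_matrix(kspace, grid_size_px)
    s = kspace.data[:, :, echo].ravel()
    f, *_ = np.linalg.lstsq(a, s, rcond=rcond)
    return np.abs(f.reshape(grid_size_px, grid_size_px))


def conjugate_phase_reconstruct(
    kspace: RadialKSpace, grid_size_px: int, echo: int = 0
) -> np.ndarray:
    """Density-compensated adjoint via the explicit DFT matrix (no FFT).

    Evaluates img(x) = sum_i w_i S_i exp(+2i pi k_i . x) directly, with the
    same ramp weights as the production path, so any disagreement with the
    gridding reconstruction isolates the kernel/FFT/deapodization
    machinery. Only feasible for grids up to ~32^2.
    """
    from .reconstruction import density_compensation

    if grid_size_px > 40:
        raise ValueError("explicit DFT oracle is limited to small grids")
    a = _encoding_matrix(kspace, grid_size_px) / (kspace.fov_mm / grid_size_px) ** 2
    w = density_compensation(kspace.trajectory, "ramp").ravel()
    s = kspace.data[:, :, echo].ravel()
    img = (w * s) @ np.conj(a)
    return np.abs(img.reshape(grid_size_px, grid_size_px))


def jt_statistic_naive(groups: list[np.ndarray]) -> float:
    """J by explicit double loops over between-group pairs (ties as 1/2)."""
    j = 0.0
    for gi in range(len(groups)):
        for gh in range(gi + 1, len(groups)):
            for a in groups[gi]:
                for b in groups[gh]:
                    if a < b:
                        j += 1.0
                    elif a == b:
                        j += 0.5
    return j


def _assignments(values: tuple, sizes: list[int]):
    """Yield every distinct split of `values` (by index) into ordered groups."""
    idx = tuple(range(len(values)))

    def rec(remaining: tuple, sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for chosen in combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in chosen)
            for tail in rec(rest, sizes_left[1:]):
                yield [chosen] + tail

    yield from rec(idx, sizes)


def jt_exact_p_enumeration(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """(J, one-sided p, two-sided p) by full enumeration of the permutation null.

    Enumerates every assignment of the pooled values to the group sizes and
    counts assignments with J at least (at most) the observed value.
    Factorially expensive; intended for pooled n <= 12.
    """
    pooled = np.concatenate(groups)
    if len(pooled) > 12:
        raise ValueError("enumeration oracle limited to pooled n <= 12")
    sizes = [len(g) for g in groups]
    j_obs = jt_statistic_naive(groups)
    total = ge = le = 0
    for assign in _assignments(tuple(pooled), sizes):
        gs = [np.asarray([pooled[i] for i in block]) for block in assign]
        j = jt_statistic_naive(gs)
        total += 1
        ge += j >= j_obs - 1e-9
        le += j <= j_obs + 1e-9
    p_ge = ge / total
    p_le = le / total
    return j_obs, p_ge, min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_exact_p_enumeration(diffs, alternative: str = "two-sided") -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are dropped first. The statistic is W+, the sum of the
    ranks of positive differences; the null flips each sign independently.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    if n > 20:
        raise ValueError("sign enumeration limited to n <= 20")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    w_total = float(ranks.sum())
    signs = np.array(
        [[(mask >> k) & 1 for k in range(n)] for mask in range(2**n)], dtype=float
    )
    w_all = signs @ ranks
    if alternative == "greater":
        return float(np.mean(w_all >= w_obs - 1e-9))
    if alternative == "less":
        return float(np.mean(w_all <= w_obs + 1e-9))
    if alternative == "two-sided":
        dev = np.abs(w_all - w_total / 2.0)
        return float(np.mean(dev >= abs(w_obs - w_total / 2.0) - 1e-9))
    raise ValueError(f"unknown alternative {alternative!r}")
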