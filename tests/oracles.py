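"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they validate: direct dense
convolution instead of separable filtering, sum-of-products Pearson r
instead of the vectorized map, and a Wishart/Bartlett sampler of the exact
correlation distribution instead of quadrature of its density.
"""

import numpy as np


def dense_gaussian_convolve(grid: np.ndarray, fwhm: float) -> np.ndarray:
    """Zero-padded 2D Gaussian convolution by explicit quadruple loop-free
    dense summation with an outer-product kernel truncated at +/- 4 sigma."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    k2 = np.outer(k1, k1)
    rows, cols = grid.shape
    out = np.zeros_like(grid, dtype=float)
    for i in range(rows):
        for j in range(cols):
            acc = 0.0
            for di in range(-radius, radius + 1):
                ii = i - di
                if not 0 <= ii < rows:
                    continue
                for dj in range(-radius, radius + 1):
                    jj = j - dj
                    if 0 <= jj < cols:
                        acc += k2[di + radius, dj + radius] * grid[ii, jj]
            out[i, j] = acc
    return out


def pearson_sums(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from raw sums of products (textbook formula)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return float(num / den)


def sample_correlations(rho: float, n: int, draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draw sample Pearson correlations at population correlation ``rho``.

    Uses the Wishart(n-1) representation of the sample covariance matrix via
    the Bartlett decomposition: S = L A A' L' with Sigma = L L', A lower
    triangular with chi distributed diagonal and standard normal
    subdiagonal. r = S12 / sqrt(S11 S22). O(draws) regardless of n.
    """
    a11 = np.sqrt(rng.chisquare(n - 1, size=draws))
    a22 = np.sqrt(rng.chisquare(n - 2, size=draws))
    a21 = rng.standard_normal(draws)
    c = np.sqrt(1.0 - rho**2)
    s11 = a11**2
    s12 = rho * a11**2 + c * a11 * a21
    s22 = rho**2 * a11**2 + 2 * rho * c * a11 * a21 + c**2 * (a21**2 + a22**2)
    return s12 / np.sqrt(s11 * s22)


def mc_power(rho: float, n: int, alpha: float, draws: int,
             rng: np.random.Generator, critical_r) -> float:
    """Monte-Carlo two-sided rejection probability of the correlation test."""
    r = sample_correlations(rho, n, draws, rng)
    return float(np.mean(np.abs(r) >= critical_r(alpha, n)))
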