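"""The core normalization model.

Per-peak MA values between two ChIP-seq samples are

    M = log2((x1 + 1) / (x2 + 1))        (log2 fold change)
    A = log2((x1 + 1) * (x2 + 1)) / 2    (mean log2 intensity)

with a +1 pseudocount on raw window counts to avoid log2(0).  Under the
assumption that most common peaks have unchanged true binding, the global
dependence M = a + b*A fitted to common peaks by robust regression (IRLS
with Tukey bisquare weights) captures the between-sample scaling and
intensity-dependent bias; normalization is the coordinate transformation
that maps this fitted line onto M = 0.

Differential binding of each peak is then scored with the Audic–Claverie
model for comparing two tag counts of the same region across libraries:
the point kernel is

    p(y | x) = (x + y)! / (x! * y! * 2^(x + y + 1))

so, conditional on the total n = x + y, the count y follows Binomial(n, 1/2)
and the reported P-value is the two-sided exact binomial tail (doubled
smaller tail, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

TUKEY_C = 4.685  # 95% Gaussian efficiency
MAD_CONSISTENCY = 1.4826
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50
_LN2 = np.log(2.0)


class DegenerateFitError(ValueError):
    """Too few points, or no spread in A, to fit the normalization line."""


class ModelDegeneracyError(ValueError):
    """|b| >= 2 makes the rescale transform singular; use residual mode."""


@dataclass(frozen=True)
class MAPoint:
    """Raw counts of one peak in both samples plus its (M, A) coordinates."""

    x1: int
    x2: int
    M: float
    A: float


@dataclass(frozen=True)
class LinearModel:
    """The common-peak robust fit M = a + b*A — the normalization reference."""

    a: float
    b: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class NormalizedPeak:
    M_norm: float
    A_norm: float
    d1_norm: float
    d2_norm: float
    p_value: float | None = None
    klass: str | None = None


def compute_ma(x1: int, x2: int) -> MAPoint:
    """MA coordinates of one peak from raw counts (pseudocount applied here)."""
    if x1 < 0 or x2 < 0:
        raise ValueError(f"counts must be >= 0, got ({x1}, {x2})")
    m, a = compute_ma_arrays(np.asarray([x1]), np.asarray([x2]))
    return MAPoint(int(x1), int(x2), float(m[0]), float(a[0]))


def compute_ma_arrays(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized M and A from raw count arrays."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("counts must be >= 0")
    t1 = np.log2(x1 + 1.0)
    t2 = np.log2(x2 + 1.0)
    return t1 - t2, (t1 + t2) / 2.0


def tukey_bisquare_weight(residual, scale: float, c: float = TUKEY_C):
    """Tukey bisquare weight (1 - u^2)^2 for u = residual/(c*scale), 0 beyond."""
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if c <= 0:
        raise ValueError(f"c must be > 0, got {c}")
    u = np.asarray(residual, dtype=np.float64) / (c * scale)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    if np.isscalar(residual):
        return float(w)
    return w


def _wls(a_vals: np.ndarray, m_vals: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(a_vals), a_vals]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(design, m_vals * sw, rcond=None)
    return coef


def fit_robust_line(points) -> LinearModel:
    """IRLS bisquare fit of M on A over the common-peak pairs.

    ``points`` may be a sequence of :class:`MAPoint` or an ``(A, M)`` array
    pair.  OLS initialization; each iteration rescales residuals by
    1.4826 * MAD (floored at 1e-8), reweights with the bisquare function at
    c = 4.685, and solves weighted least squares; stops when the largest
    coefficient change is below 1e-8 or after 50 iterations.
    """
    if isinstance(points, tuple) and len(points) == 2:
        a_vals = np.asarray(points[0], dtype=np.float64)
        m_vals = np.asarray(points[1], dtype=np.float64)
    else:
        pts = list(points)
        a_vals = np.asarray([p.A for p in pts], dtype=np.float64)
        m_vals = np.asarray([p.M for p in pts], dtype=np.float64)
    n = a_vals.size
    if n < 2:
        raise DegenerateFitError(f"need >= 2 common-peak points, got {n}")
    if np.ptp(a_vals) == 0:
        raise DegenerateFitError("all A values identical; line is not identifiable")

    design = np.column_stack([np.ones_like(a_vals), a_vals])
    coef, *_ = np.linalg.lstsq(design, m_vals, rcond=None)
    converged = False
    for _ in range(IRLS_MAX_ITER):
        resid = m_vals - design @ coef
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(MAD_CONSISTENCY * mad, 1e-8)
        w = tukey_bisquare_weight(resid, scale)
        if np.count_nonzero(w) < 2:
            break  # pathological: everything downweighted to zero
        new_coef = _wls(a_vals, m_vals, w)
        delta = np.max(np.abs(new_coef - coef))
        coef = new_coef
        if delta < IRLS_TOL:
            converged = True
            break
    return LinearModel(float(coef[0]), float(coef[1]), int(n), converged)


def normalize_all(
    x1: np.ndarray, x2: np.ndarray, model: LinearModel, mode: str = "rescale"
) -> dict[str, np.ndarray]:
    """Map all peaks' counts into normalized MA coordinates.

    ``rescale`` (default) anchors sample 2 and rescales sample 1's log
    density so that the fitted line lands on M = 0:

        t1' = ((2 - b) * t1 - 2a) / (2 + b),   t2' = t2

    ``residual`` subtracts the fitted trend, split symmetrically between the
    two samples so normalized densities remain defined and sample order does
    not matter:

        t1' = t1 - (a + b*A)/2,   t2' = t2 + (a + b*A)/2

    Both modes map any point lying exactly on the fitted line to M_norm = 0.
    Returns arrays ``M_norm, A_norm, d1_norm, d2_norm`` (densities on the
    pseudocount scale, 2**t').
    """
    if mode not in ("rescale", "residual"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    t1 = np.log2(x1 + 1.0)
    t2 = np.log2(x2 + 1.0)
    a, b = model.a, model.b
    if mode == "rescale":
        if abs(b) >= 2:
            raise ModelDegeneracyError(
                f"|slope| = {abs(b):.3g} >= 2 makes the rescale transform "
                "singular; rerun in residual mode"
            )
        t1n = ((2.0 - b) * t1 - 2.0 * a) / (2.0 + b)
        t2n = t2
    else:
        correction = (a + b * ((t1 + t2) / 2.0)) / 2.0
        t1n = t1 - correction
        t2n = t2 + correction
    return {
        "M_norm": t1n - t2n,
        "A_norm": (t1n + t2n) / 2.0,
        "d1_norm": 2.0**t1n,
        "d2_norm": 2.0**t2n,
    }


def ac_point_prob(x: int, y: int) -> float:
    """Audic–Claverie point kernel (x+y)!/(x! y! 2^(x+y+1)), in log space."""
    if x < 0 or y < 0:
        raise ValueError(f"counts must be >= 0, got ({x}, {y})")
    return float(
        np.exp(
            gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1) - (x + y + 1) * _LN2
        )
    )


def ac_pvalue(x: int, y: int) -> float:
    """Two-sided Audic–Claverie P-value for normalized counts (x, y).

    Conditional on n = x + y the count y is Binomial(n, 1/2); the P-value is
    twice the smaller exact tail (each tail includes the observed point),
    capped at 1.  Both tails are evaluated as lower-tail sums — P(>= y) is
    summed as P(<= x) via pmf symmetry — so the result is exactly symmetric
    in (x, y).
    """
    if x < 0 or y < 0:
        raise ValueError(f"counts must be >= 0, got ({x}, {y})")
    n = x + y
    if n == 0:
        return 1.0
    k = np.arange(n + 1)
    logpmf = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) - n * _LN2
    lower = logsumexp(logpmf[: y + 1])  # P(Y <= y)
    upper = logsumexp(logpmf[: x + 1])  # P(Y >= y) == P(Y <= x)
    return min(1.0, 2.0 * float(np.exp(min(lower, upper))))


def normalized_counts(d1_norm: np.ndarray, d2_norm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer counts for the AC test: undo the +1 pseudocount and round."""
    x = np.maximum(0, np.rint(np.asarray(d1_norm) - 1.0)).astype(np.int64)
    y = np.maximum(0, np.rint(np.asarray(d2_norm) - 1.0)).astype(np.int64)
    return x, y


def ac_pvalues(d1_norm: np.ndarray, d2_norm: np.ndarray) -> np.ndarray:
    """Vectorized AC P-values from normalized densities."""
    x, y = normalized_counts(d1_norm, d2_norm)
    return np.asarray([ac_pvalue(int(xi), int(yi)) for xi, yi in zip(x, y)])


def classify_differential(
    m_norm: np.ndarray,
    p_values: np.ndarray,
    m_cutoff: float = 1.0,
    p_cutoff: float = 0.01,
) -> np.ndarray:
    """Label peaks sample1_biased / sample2_biased / unbiased.

    A peak is biased toward a sample when its normalized M passes the
    (absolute) M cutoff in that direction AND its P-value passes the cutoff.
    """
    if m_cutoff < 0:
        raise ValueError(f"m_cutoff must be >= 0, got {m_cutoff}")
    if not (0 < p_cutoff <= 1):
        raise ValueError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    m_norm = np.asarray(m_norm)
    p_values = np.asarray(p_values)
    sig = p_values <= p_cutoff
    mask1 = (m_norm >= m_cutoff) & sig
    mask2 = (m_norm <= -m_cutoff) & sig
    # at m_cutoff == 0 a peak with M_norm == 0 satisfies both: keep it unbiased
    both = mask1 & mask2
    out = np.full(m_norm.shape, "unbiased", dtype=object)
    out[mask1 & ~both] = "sample1_biased"
    out[mask2 & ~both] = "sample2_biased"
    return out
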