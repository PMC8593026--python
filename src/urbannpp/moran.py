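"""Global and local Moran's I with normality, randomization and permutation inference.

The global statistic over cells i = 1..n with deviations z_i = Y_i - Ybar is

    I = (n / W0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),      W0 = sum_ij w_ij,

with null expectation E(I) = -1/(n-1). Two analytic variances are reported:
the normality (Gaussian) variance and the randomization variance, both in
their standard Cliff-Ord forms built from the weight sums S1 and S2. The
headline inference is a permutation test: values are randomly reassigned to
cells and the two-sided pseudo p-value is (exceedances + 1)/(n_perm + 1).

The local statistic I_i = (z_i / m2) * sum_j w_ij z_j, with m2 = sum z^2 / n,
satisfies sum_i I_i = I * W0 and is tested by conditional permutation: cell
i's value is held fixed while the remaining n-1 values are shuffled onto its
neighbor positions. Significant cells are classified by the quadrant of
(z_i, spatial lag): HH, LL, LH or HL; all others are NS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .weights import SpatialWeights

LISA_CLASSES = ("NS", "HH", "LL", "LH", "HL")


@dataclass
class MoranResult:
    I: float
    E_I: float
    var_norm: float
    var_rand: float
    z_norm: float
    z_rand: float
    p_norm: float
    n: int
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    perm_mean: float | None = None
    perm_sd: float | None = None


@dataclass
class LisaResult:
    I_i: np.ndarray          # per-cell local Moran; NaN where undefined
    p_i: np.ndarray          # conditional-permutation pseudo p; NaN where undefined
    z: np.ndarray            # deviations Y_i - Ybar
    lag: np.ndarray          # spatial lag of z
    E_i: np.ndarray          # conditional expectation of I_i
    n_perm: int
    seed: int | None


def _prepare(values, w: SpatialWeights) -> np.ndarray:
    y = np.asarray(values, dtype=float).ravel()
    if y.size != w.n:
        raise ValueError(f"values length {y.size} does not match weights n={w.n}")
    if y.size < 3:
        raise ValueError(f"at least 3 cells required, got {y.size}")
    if not np.isfinite(y).all():
        raise ValueError("values must be finite for Moran analysis")
    if np.ptp(y) == 0:
        raise ValueError("zero variance: the field is constant over all cells")
    return y


def _moran_stat(z: np.ndarray, w: SpatialWeights) -> float:
    return float(z.size / w.W0 * (z @ (w.W @ z)) / (z @ z))


def global_morans_i(values, w: SpatialWeights) -> MoranResult:
    """Global Moran's I with normality and randomization Z-scores.

    Both analytic variances (Gaussian-sampling and randomization) are
    reported; ``p_norm`` is the two-sided normal p-value under the
    normality variance.
    """
    y = _prepare(values, w)
    n = y.size
    z = y - y.mean()
    I = _moran_stat(z, w)
    E = -1.0 / (n - 1)
    W0, S1, S2 = w.W0, w.S1, w.S2

    var_norm = (n * n * S1 - n * S2 + 3 * W0 * W0) / (W0 * W0 * (n * n - 1)) - E * E

    z2 = z @ z
    b2 = n * (z ** 4).sum() / (z2 * z2)
    num = n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * W0 * W0) \
        - b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * W0 * W0)
    var_rand = num / ((n - 1) * (n - 2) * (n - 3) * W0 * W0) - E * E

    z_norm = (I - E) / np.sqrt(var_norm)
    z_rand = (I - E) / np.sqrt(var_rand) if var_rand > 0 else float("nan")
    p_norm = 2.0 * stats.norm.sf(abs(z_norm))
    if not (-1.0 - 1e-9 <= I <= 1.0 + 1e-9):
        # possible for irregular weight structures; flagged, not an error
        import logging

        logging.getLogger(__name__).warning("Moran's I = %.6f outside [-1, 1]", I)
    return MoranResult(I=I, E_I=E, var_norm=var_norm, var_rand=var_rand,
                       z_norm=float(z_norm), z_rand=float(z_rand),
                       p_norm=float(p_norm), n=n)


def permutation_test_global(
    values, w: SpatialWeights, n_perm: int = 999, seed: int | None = None
) -> MoranResult:
    """Permutation inference for global Moran's I.

    Values are permuted across cells ``n_perm`` times; the two-sided pseudo
    p-value counts permuted statistics at least as far from E(I) as the
    observed one, so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    res = global_morans_i(values, w)
    y = np.asarray(values, dtype=float).ravel()
    z = y - y.mean()
    n = z.size
    rng = np.random.default_rng(seed)

    z2 = z @ z
    perm_I = np.empty(n_perm)
    batch = max(1, min(n_perm, 512))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)  # b random permutations
        Z = z[idx].T  # (n, b)
        perm_I[done:done + b] = n / w.W0 * np.einsum("ib,ib->b", Z, w.W @ Z) / z2
        done += b

    exceed = int((np.abs(perm_I - res.E_I) >= np.abs(res.I - res.E_I) - 1e-14).sum())
    res.p_perm = (exceed + 1) / (n_perm + 1)
    res.n_perm = n_perm
    res.seed = seed
    res.perm_mean = float(perm_I.mean())
    res.perm_sd = float(perm_I.std(ddof=1))
    return res


def local_morans_i(
    values, w: SpatialWeights, n_perm: int = 999, seed: int | None = None
) -> LisaResult:
    """Local Moran's I per cell with conditional-permutation p-values.

    Cells without neighbors have undefined I_i (NaN) and are excluded from
    classification. The conditional scheme holds cell i's value fixed and
    draws its neighbors' values from the remaining n-1 cells without
    replacement, reusing one seed-fixed set of permutation prefixes across
    cells (the classic LISA implementation strategy).
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    y = _prepare(values, w)
    n = y.size
    z = y - y.mean()
    m2 = (z @ z) / n
    lag = w.W @ z
    card = w.cardinalities
    rowsum = np.asarray(w.W.sum(axis=1)).ravel()

    I_i = np.where(card > 0, z * lag / m2, np.nan)
    E_i = np.where(card > 0, -(z ** 2) * rowsum / (m2 * (n - 1)), np.nan)

    rng = np.random.default_rng(seed)
    kmax = int(card.max())
    # shared permutation prefixes of {0..n-2}; per cell they index the other cells
    prefixes = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :kmax]

    p_i = np.full(n, np.nan)
    indptr, indices, data = w.W.indptr, w.W.indices, w.W.data
    all_ids = np.arange(n)
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k == 0:
            continue
        wts = data[indptr[i]:indptr[i + 1]]
        others = np.delete(all_ids, i)
        zsamp = z[others[prefixes[:, :k]]]       # (n_perm, k)
        I_perm = z[i] * (zsamp @ wts) / m2
        obs_dev = abs(I_i[i] - E_i[i])
        exceed = int((np.abs(I_perm - E_i[i]) >= obs_dev - 1e-14).sum())
        p_i[i] = (exceed + 1) / (n_perm + 1)

    return LisaResult(I_i=I_i, p_i=p_i, z=z, lag=lag, E_i=E_i,
                      n_perm=n_perm, seed=seed)


def lisa_classify(lisa: LisaResult, alpha: float = 0.05) -> np.ndarray:
    """Classify cells into NS/HH/LL/LH/HL by significance and quadrant.

    NS wherever p_i >= alpha (strict inequality required for significance)
    or where I_i is undefined; otherwise the class follows the signs of
    (z_i, lag_i): (+,+)->HH, (-,-)->LL, (-,+)->LH, (+,-)->HL.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    classes = np.full(lisa.z.size, "NS", dtype=object)
    sig = np.isfinite(lisa.p_i) & (lisa.p_i < alpha)
    pos_z = lisa.z > 0
    pos_lag = lisa.lag > 0
    classes[sig & pos_z & pos_lag] = "HH"
    classes[sig & ~pos_z & ~pos_lag] = "LL"
    classes[sig & ~pos_z & pos_lag] = "LH"
    classes[sig & pos_z & ~pos_lag] = "HL"
    return classes
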