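"""Multivariate regression of shape on a scalar predictor, pooled within strata.

The model is a single slope shared across strata (typically the sexes): both
the tangent-space shape coordinates and the predictor are centered by their
stratum means, and one coefficient matrix ``beta`` (shape change per unit
predictor, Procrustes units) is fitted to the pooled deviations.  This is the
standard pooled within-group regression used to estimate allometric and other
size-driven shape patterns while holding sexual dimorphism out of the slope.

Significance is assessed by permuting predictor values within strata (the
superimposition is held fixed — it does not depend on the predictor), with the
predicted sum of squares as test statistic and the add-one p-value convention
p = (1 + #{perm >= obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpa import ProcrustesResult, mean_shape

__all__ = [
    "ShapeRegressionModel",
    "pooled_within_regression",
    "regression_scores",
    "percent_variance_explained",
    "predict_shape",
    "predicted_shape_change",
    "permutation_test_regression",
    "coefficient_of_variation",
]


@dataclass
class ShapeRegressionModel:
    """Fitted pooled-within-stratum regression of shape on one predictor."""

    predictor_name: str
    beta: np.ndarray            # (k, d) shape change per unit predictor
    consensus: np.ndarray       # (k, d) mean shape of the superimposition
    strata: np.ndarray          # stratum label per specimen
    x_mean: float               # grand mean of the predictor
    percent_var: float          # % of total tangent-space variance explained
    p_value: float | None       # permutation p-value (None if n_perm == 0)
    n_perm: int
    seed: int | None
    ss_total: float = field(repr=False, default=np.nan)

    @property
    def beta_norm(self) -> float:
        return float(np.linalg.norm(self.beta.ravel()))


def _aligned_and_consensus(aligned) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(aligned, ProcrustesResult):
        return aligned.aligned, aligned.consensus
    arr = np.asarray(aligned, dtype=float)
    return arr, mean_shape(arr)


def _stratum_center(Y: np.ndarray, x: np.ndarray, strata: np.ndarray):
    """Center flattened shapes and predictor by stratum means."""
    Yt = Y.copy()
    xt = x.astype(float).copy()
    for lab in np.unique(strata):
        m = strata == lab
        if m.sum() < 2:
            raise ValueError(
                f"stratum {lab!r} has {int(m.sum())} member(s); need >= 2 "
                "(singleton deviations are identically zero)"
            )
        Yt[m] -= Yt[m].mean(axis=0)
        xt[m] -= xt[m].mean()
    return Yt, xt


def _validate_inputs(Y: np.ndarray, x: np.ndarray, strata: np.ndarray):
    n = Y.shape[0]
    x = np.asarray(x, dtype=float)
    strata = np.asarray(strata)
    if x.shape != (n,) or strata.shape != (n,):
        raise ValueError(
            f"predictor/strata lengths ({x.shape}, {strata.shape}) do not "
            f"match {n} specimens"
        )
    if n < 3:
        raise ValueError("regression needs at least 3 specimens")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite predictor values")
    return x, strata


def pooled_within_regression(
    aligned,
    x,
    strata,
    n_perm: int = 5000,
    seed: int | None = None,
    predictor_name: str = "predictor",
) -> ShapeRegressionModel:
    """Fit shape ~ predictor with stratum-mean centering of both sides.

    Parameters
    ----------
    aligned : ProcrustesResult or (n, k, d) array
        Tangent-space shape coordinates.
    x : (n,) array
        Predictor on its analysis scale (cube-root mm for brain size, mm for
        chondrocranial length, log units for overall size).
    strata : (n,) array
        Pooling labels, typically sex.
    n_perm : int
        Within-stratum permutations for the p-value; 0 skips the test.
    seed : int
        Seed for the permutation stream (required when n_perm > 0).
    """
    A, consensus = _aligned_and_consensus(aligned)
    n = A.shape[0]
    x, strata = _validate_inputs(A, x, strata)
    Y = A.reshape(n, -1)
    Yt, xt = _stratum_center(Y, x, strata)
    sxx = float(xt @ xt)
    if sxx <= 0.0:
        raise ValueError("zero pooled predictor variance")
    beta_flat = (xt @ Yt) / sxx
    ss_pred = sxx * float(beta_flat @ beta_flat)
    ss_total = float((Yt**2).sum())
    if ss_total == 0.0:
        raise ValueError("zero total shape variance: all shapes identical")
    percent_var = 100.0 * ss_pred / ss_total

    p_value = None
    if n_perm > 0:
        p_value = permutation_test_regression(
            A, x, strata, n_perm=n_perm, seed=seed
        )
    return ShapeRegressionModel(
        predictor_name=predictor_name,
        beta=beta_flat.reshape(consensus.shape),
        consensus=consensus,
        strata=strata,
        x_mean=float(x.mean()),
        percent_var=percent_var,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
        ss_total=ss_total,
    )


def permutation_test_regression(
    aligned, x, strata, n_perm: int = 5000, seed: int | None = None
) -> float:
    """Within-stratum permutation p-value for the shape regression.

    The test statistic is the predicted sum of squares; the pooled predictor
    sum of squares is permutation-invariant, so comparing ``||Yt' xt||^2``
    across permutations is equivalent.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    A, _ = _aligned_and_consensus(aligned)
    n = A.shape[0]
    x, strata = _validate_inputs(A, x, strata)
    Y = A.reshape(n, -1)
    Yt, xt = _stratum_center(Y, x, strata)
    obs = float(((xt @ Yt) ** 2).sum())

    rng = np.random.default_rng(seed)
    groups = [np.nonzero(strata == lab)[0] for lab in np.unique(strata)]
    P = np.tile(xt, (n_perm, 1))
    for idx in groups:
        for r in range(n_perm):
            P[r, idx] = P[r, idx[rng.permutation(idx.size)]]
    stats = ((P @ Yt) ** 2).sum(axis=1)
    return float((1 + int((stats >= obs).sum())) / (n_perm + 1))


def regression_scores(aligned, model: ShapeRegressionModel) -> np.ndarray:
    """Project each specimen's deviation from the consensus onto beta.

    Scores are inner products with the unit-normalised coefficient vector, so
    they are in Procrustes units; deviations are *not* stratum-centered
    (individual scores are along the pooled vector, dimorphism included).
    """
    A, _ = _aligned_and_consensus(aligned)
    b = model.beta.ravel()
    nb = np.linalg.norm(b)
    if nb == 0.0:
        raise ValueError("zero coefficient vector: no axis to project on")
    dev = A.reshape(A.shape[0], -1) - model.consensus.ravel()
    return dev @ (b / nb)


def percent_variance_explained(aligned, x, strata) -> float:
    """Percent of total tangent-space variance explained by the predictor."""
    model = pooled_within_regression(aligned, x, strata, n_perm=0)
    return model.percent_var


def predict_shape(model: ShapeRegressionModel, x: float) -> np.ndarray:
    """Predicted shape at predictor value x: consensus + (x - mean) * beta."""
    return model.consensus + (float(x) - model.x_mean) * model.beta


def predicted_shape_change(model: ShapeRegressionModel, delta_x: float) -> float:
    """Procrustes distance between predicted shapes delta_x apart.

    ``delta_x`` is on the predictor's analysis scale (e.g. a difference of
    cube-root volumes in mm, never a raw-volume percentage).
    """
    return abs(float(delta_x)) * model.beta_norm


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    m = v.mean()
    if m == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / m)
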