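"""Group mean-shape contrasts and the funneling comparison.

A mutation's average effect on shape is the difference between the mutant and
wildtype mean shapes, computed after a *joint* superimposition of all
specimens (Procrustes distance between means is only defined in a common
space).  Its size is the Procrustes distance between the means; significance
comes from permuting group labels with the superimposition held fixed.

The funneling comparison asks whether a mutant's observed shape displacement
matches the displacement predicted from normal variation: the regression of
shape on the perturbed predictor, evaluated at the mutant's predictor shift.
Agreement (ratio near 1, small angle) supports the hypothesis that the
mutation acts on shape through that predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpa import ProcrustesResult
from .regression import ShapeRegressionModel, predicted_shape_change

__all__ = [
    "ContrastResult",
    "group_contrast",
    "predictor_shift",
    "funneling_comparison",
    "vector_angle",
]


@dataclass
class ContrastResult:
    """Mean-difference effect vector between two groups."""

    ref_group: str
    alt_group: str
    effect_vector: np.ndarray      # (k, d): alt mean - ref mean
    distance: float                # Procrustes units
    p_value: float | None
    n_perm: int
    seed: int | None
    n_ref: int
    n_alt: int
    ref_mean: np.ndarray
    alt_mean: np.ndarray
    predictor_name: str | None = None
    predictor_shift: float | None = None       # analysis scale
    predictor_shift_pct: float | None = None   # % of ref mean, raw scale


def group_contrast(
    aligned,
    groups,
    ref: str,
    alt: str,
    n_perm: int = 5000,
    seed: int | None = None,
) -> ContrastResult:
    """Effect vector, Procrustes distance and permutation p for alt vs ref.

    ``aligned`` is a ProcrustesResult (or (n, k, d) array) from a joint
    superimposition of all specimens; ``groups`` labels each specimen.
    Specimens outside the two groups are ignored by the statistic and by the
    label permutation.
    """
    A = aligned.aligned if isinstance(aligned, ProcrustesResult) else np.asarray(aligned, dtype=float)
    groups = np.asarray(groups)
    if groups.shape[0] != A.shape[0]:
        raise ValueError("group labels do not match number of specimens")
    for g in (ref, alt):
        if not np.any(groups == g):
            raise ValueError(f"unknown or empty group {g!r}")
    mref = groups == ref
    malt = groups == alt
    Y = A.reshape(A.shape[0], -1)
    ref_mean = Y[mref].mean(axis=0)
    alt_mean = Y[malt].mean(axis=0)
    diff = alt_mean - ref_mean
    distance = float(np.linalg.norm(diff))

    p_value = None
    if n_perm > 0:
        if seed is None:
            raise ValueError("a seed is required for the permutation test")
        rng = np.random.default_rng(seed)
        sel = np.nonzero(mref | malt)[0]
        is_alt = malt[sel]
        n_alt = int(is_alt.sum())
        Ysub = Y[sel]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(sel.size)
            palt = np.zeros(sel.size, dtype=bool)
            palt[perm[:n_alt]] = True
            d = Ysub[palt].mean(axis=0) - Ysub[~palt].mean(axis=0)
            if float(np.linalg.norm(d)) >= distance:
                count += 1
        p_value = (1 + count) / (n_perm + 1)

    shape = A.shape[1:]
    return ContrastResult(
        ref_group=ref,
        alt_group=alt,
        effect_vector=diff.reshape(shape),
        distance=distance,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
        n_ref=int(mref.sum()),
        n_alt=int(malt.sum()),
        ref_mean=ref_mean.reshape(shape),
        alt_mean=alt_mean.reshape(shape),
    )


def predictor_shift(
    metadata: pd.DataFrame,
    predictor_name: str,
    ref: str,
    alt: str,
    scale: str = "analysis",
    group_column: str = "group",
) -> float:
    """Difference of group means of a predictor column.

    ``scale='analysis'`` returns mean(alt) - mean(ref) of the column as is
    (pass the analysis-scale column, e.g. cube-root volume).
    ``scale='percent'`` returns 100 * (mean(alt) - mean(ref)) / mean(ref)
    (pass the raw, untransformed measurement column).
    """
    if predictor_name not in metadata.columns:
        raise KeyError(f"no metadata column {predictor_name!r}")
    vals = pd.to_numeric(metadata[predictor_name], errors="coerce")
    if vals.isna().any():
        bad = metadata.loc[vals.isna(), "specimen_id"].tolist()
        raise ValueError(f"missing {predictor_name!r} values for specimens {bad}")
    g = metadata[group_column].astype(str)
    for lab in (ref, alt):
        if not (g == lab).any():
            raise ValueError(f"unknown or empty group {lab!r}")
    m_ref = float(vals[g == ref].mean())
    m_alt = float(vals[g == alt].mean())
    if scale == "analysis":
        return m_alt - m_ref
    if scale == "percent":
        if m_ref == 0.0:
            raise ValueError("percent shift undefined: reference mean is zero")
        return 100.0 * (m_alt - m_ref) / m_ref
    raise ValueError(f"scale must be 'analysis' or 'percent', got {scale!r}")


def vector_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two shape vectors (flattened), in [0, 180]."""
    a = np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angle undefined for a zero vector")
    u, w = a / na, b / nb
    # atan2 form is exact at 0/180 deg where arccos loses precision
    theta = 2.0 * np.arctan2(np.linalg.norm(u - w), np.linalg.norm(u + w))
    return float(np.degrees(theta))


def funneling_comparison(
    contrast: ContrastResult, model: ShapeRegressionModel
) -> dict:
    """Observed vs regression-predicted shape change for one mutant contrast.

    Requires ``contrast.predictor_shift`` (analysis scale) to be set.  The
    angle is between the contrast effect vector and the regression
    coefficient vector, both expressed in the same shared shape space — this
    is only meaningful within one superimposition (e.g. one species), never
    across species with large mean-shape differences.
    """
    if contrast.predictor_shift is None:
        raise ValueError("contrast has no predictor_shift; compute it first")
    if model.beta_norm == 0.0:
        raise ValueError("regression coefficient vector is zero")
    predicted = predicted_shape_change(model, contrast.predictor_shift)
    angle = vector_angle(contrast.effect_vector, model.beta)
    # orient the angle with the sign of the shift: a negative predictor shift
    # should displace shapes along -beta, so compare against that direction
    if contrast.predictor_shift < 0:
        angle = 180.0 - angle
    return {
        "ref_group": contrast.ref_group,
        "alt_group": contrast.alt_group,
        "predictor": model.predictor_name,
        "observed_distance": contrast.distance,
        "predicted_distance": predicted,
        "ratio_observed_over_predicted": contrast.distance / predicted,
        "angle_degrees": angle,
        "predictor_shift": contrast.predictor_shift,
        "predictor_shift_pct": contrast.predictor_shift_pct,
    }
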