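"""Synthetic landmark populations with known generative structure.

The generator produces exactly the data-generating process the analysis
assumes: a mean shape, linear shape effects in tangent space driven by latent
size predictors (brain size, chondrocranial length, overall size), an
additive sexual-dimorphism offset, isotropic per-coordinate landmark noise,
and per-specimen nuisance similarity transforms (rotation, translation,
scale) that GPA must remove.  Because the truth (effect vectors, slopes,
predictor values) is recorded, every downstream stage — superimposition,
pooled regression, mutant contrasts, the funneling comparison — can be tested
for parameter recovery without the study's specimens.

The built-in template is an 18-landmark, 3D half-cranium-like configuration
using standard cranial landmark names.  Its coordinates are fixed, plausible
constants with no anatomical authority; they exist so simulations and tests
are deterministic and so named-landmark predictors (hormion–opisthocranion
distance) are defined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .gpa import centroid_size, interlandmark_distance
from .landmark_io import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "TEMPLATE_LANDMARK_NAMES",
    "TEMPLATE",
    "EffectSpec",
    "SimulationSpec",
    "default_effect_vector",
    "simulate_population",
    "simulate_mutant_pair",
    "measure_predictors",
    "mouse_study_spec",
    "remove_similarity_components",
]

TEMPLATE_LANDMARK_NAMES: tuple[str, ...] = (
    "nasion",
    "glabella",
    "bregma",
    "lambda",
    "opisthocranion",
    "inion",
    "opisthion",
    "basion",
    "hormion",
    "prosthion",
    "subspinale",
    "zygoorbitale",
    "frontomalare",
    "zygomaxillare",
    "euryon",
    "asterion",
    "porion",
    "pterion",
)

# x: anterior(+)/posterior(-), y: lateral (left, >= 0 off midline), z: superior(+)
_TEMPLATE_RAW = np.array(
    [
        [9.0, 0.0, 5.0],      # nasion
        [9.5, 0.0, 6.5],      # glabella
        [3.0, 0.0, 12.0],     # bregma
        [-6.0, 0.0, 10.0],    # lambda
        [-9.0, 0.0, 4.0],     # opisthocranion
        [-8.5, 0.0, 2.0],     # inion
        [-7.0, 0.0, -1.0],    # opisthion
        [-5.0, 0.0, -2.0],    # basion
        [1.0, 0.0, -1.5],     # hormion
        [8.5, 0.0, -3.0],     # prosthion
        [8.8, 0.0, -1.5],     # subspinale
        [7.5, 2.5, 2.5],      # zygoorbitale
        [7.0, 4.0, 5.0],      # frontomalare
        [6.5, 4.5, 0.0],      # zygomaxillare
        [-2.0, 7.0, 6.0],     # euryon
        [-6.0, 5.0, 2.0],     # asterion
        [-2.5, 6.0, -0.5],    # porion
        [3.0, 5.5, 7.0],      # pterion
    ]
)

_centered = _TEMPLATE_RAW - _TEMPLATE_RAW.mean(axis=0)
#: built-in mean shape, centered, unit centroid size
TEMPLATE: np.ndarray = _centered / np.sqrt((_centered**2).sum())
TEMPLATE.setflags(write=False)

_IDX = {name: i for i, name in enumerate(TEMPLATE_LANDMARK_NAMES)}
_BRAINCASE = ("bregma", "lambda", "opisthocranion", "inion", "euryon",
              "asterion", "porion", "pterion")
_FACE = ("nasion", "glabella", "prosthion", "subspinale", "zygoorbitale",
         "frontomalare", "zygomaxillare")


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows, flattened) of the similarity directions at a shape.

    Spans translations (d), uniform scaling (1) and infinitesimal rotations
    (d(d-1)/2) — the directions GPA removes; effect vectors are built
    orthogonal to them so nominal slopes survive superimposition.
    """
    k, d = template.shape
    vecs = []
    for j in range(d):
        t = np.zeros((k, d))
        t[:, j] = 1.0
        vecs.append(t.ravel())
    vecs.append(template.ravel())
    for i in range(d):
        for j in range(i + 1, d):
            A = np.zeros((d, d))
            A[i, j] = 1.0
            A[j, i] = -1.0
            vecs.append((template @ A).ravel())
    B = np.array(vecs)
    # orthonormalise (rotation generators are not orthogonal to each other in general)
    Q, _ = np.linalg.qr(B.T)
    return Q.T[: len(vecs)]


def remove_similarity_components(vector: np.ndarray, template: np.ndarray = None) -> np.ndarray:
    """Project a shape vector onto the complement of the similarity directions."""
    if template is None:
        template = TEMPLATE
    v = np.asarray(vector, dtype=float).ravel().copy()
    for b in _similarity_basis(template):
        v -= (v @ b) * b
    return v.reshape(template.shape)


def _build_default_vectors() -> dict[str, np.ndarray]:
    """Deterministic unit effect vectors on the built-in template.

    brain_size   — braincase landmarks displaced outward from the braincase
                   centroid (vault expansion);
    chondro_length — hormion and opisthocranion displaced apart along their
                   axis, with a compensatory downward shift of bregma
                   (lengthening flattens the vault);
    log_centroid_size — allometry: face outward from the centroid, braincase
                   inward (relative facial enlargement in bigger skulls);
    sex          — mild prognathism contrast (nasion/glabella forward, inion
                   back).

    All vectors are projected off the similarity directions, orthogonalised
    against each other in the order above, and normalised to unit length.
    """
    t = TEMPLATE
    raw: dict[str, np.ndarray] = {}

    v = np.zeros_like(t)
    bc = np.array([_IDX[n] for n in _BRAINCASE])
    center = t[bc].mean(axis=0)
    v[bc] = t[bc] - center
    raw["brain_size"] = v

    v = np.zeros_like(t)
    h, o = _IDX["hormion"], _IDX["opisthocranion"]
    axis = t[h] - t[o]
    axis = axis / np.linalg.norm(axis)
    v[h] = axis
    v[o] = -axis
    # the separation/doming mix is calibrated so that, at the default slope
    # and base scale, 1 mm of the latent changes the measured hormion-
    # opisthocranion distance by 1 mm (the latent IS that length)
    v[_IDX["bregma"]] = np.array([0.0, 0.0, -3.4475])
    raw["chondro_length"] = v

    v = np.zeros_like(t)
    fc = np.array([_IDX[n] for n in _FACE])
    v[fc] = t[fc] - t[fc].mean(axis=0)
    v[bc] = -(t[bc] - center) * 0.5
    raw["log_centroid_size"] = v

    v = np.zeros_like(t)
    v[_IDX["nasion"]] = [0.5, 0.0, 0.0]
    v[_IDX["glabella"]] = [0.5, 0.0, 0.0]
    v[_IDX["inion"]] = [-0.5, 0.0, 0.0]
    raw["sex"] = v

    out: dict[str, np.ndarray] = {}
    done: list[np.ndarray] = []
    for name in ("brain_size", "chondro_length", "log_centroid_size", "sex"):
        v = remove_similarity_components(raw[name]).ravel()
        for u in done:
            v -= (v @ u) * u
        v /= np.linalg.norm(v)
        done.append(v)
        out[name] = v.reshape(t.shape)
        out[name].setflags(write=False)
    return out


_DEFAULT_VECTORS = _build_default_vectors()


def default_effect_vector(name: str) -> np.ndarray:
    """Built-in unit effect vector by name (brain_size, chondro_length,
    log_centroid_size, sex)."""
    try:
        return _DEFAULT_VECTORS[name]
    except KeyError:
        raise KeyError(
            f"no built-in vector {name!r}; available: {sorted(_DEFAULT_VECTORS)}"
        ) from None


@dataclass(frozen=True)
class EffectSpec:
    """One latent predictor with a linear shape effect.

    The stored vector is unit-norm (an input vector is normalised and its
    norm folded into ``slope``).  ``mean``/``sd`` parameterise the latent's
    normal distribution on the analysis scale; ``ref_mean`` is the reference
    value the shape effect is anchored at (defaults to ``mean``; mutant
    groups shift ``mean`` while keeping ``ref_mean``, so their shapes are
    displaced).  ``sets_scale`` marks the latent as the log of the specimen's
    raw scale (used for the overall-size predictor).
    """

    name: str
    vector: np.ndarray
    slope: float
    mean: float
    sd: float
    ref_mean: float | None = None
    sets_scale: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        norm = float(np.linalg.norm(v.ravel()))
        if norm == 0.0:
            raise ValueError(f"effect {self.name!r}: zero vector")
        object.__setattr__(self, "vector", v / norm)
        object.__setattr__(self, "slope", float(self.slope) * norm)
        if self.sd < 0:
            raise ValueError(f"effect {self.name!r}: negative sd")

    @property
    def anchor(self) -> float:
        return self.mean if self.ref_mean is None else self.ref_mean


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated population.

    Nuisance transforms: a uniform random proper rotation (if ``rotate``),
    a uniform translation in ``[-translation, translation]`` per axis, and a
    scale of ``base_scale`` (or ``exp(latent)`` when an effect has
    ``sets_scale``) times ``exp(N(0, scale_jitter))``.
    """

    n: int
    seed: int
    effects: tuple[EffectSpec, ...] = ()
    template: np.ndarray = field(default_factory=lambda: TEMPLATE)
    landmark_names: tuple[str, ...] = TEMPLATE_LANDMARK_NAMES
    sex_offset: np.ndarray | None = None
    male_fraction: float = 0.5
    noise_sd: float = 0.0
    base_scale: float = 30.0
    rotate: bool = True
    translation: float = 50.0
    scale_jitter: float = 0.0
    group: str = "wildtype"
    mean_displacement: np.ndarray | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.n < 2:
            problems.append(f"n must be >= 2 (got {self.n})")
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.noise_sd < 0:
            problems.append(f"noise_sd must be >= 0 (got {self.noise_sd})")
        if not 0.0 <= self.male_fraction <= 1.0:
            problems.append(f"male_fraction must be in [0, 1] (got {self.male_fraction})")
        if self.base_scale <= 0:
            problems.append(f"base_scale must be > 0 (got {self.base_scale})")
        t = np.asarray(self.template, dtype=float)
        object.__setattr__(self, "template", t)
        if t.ndim != 2 or t.shape[1] not in (2, 3):
            problems.append(f"template must be (k, 2|3), got {t.shape}")
        elif len(self.landmark_names) != t.shape[0]:
            problems.append("landmark_names length does not match template")
        n_scale = sum(e.sets_scale for e in self.effects)
        if n_scale > 1:
            problems.append("at most one effect may set the specimen scale")
        for e in self.effects:
            if e.vector.shape != t.shape:
                problems.append(f"effect {e.name!r}: vector shape {e.vector.shape} != template {t.shape}")
        if self.sex_offset is not None:
            so = np.asarray(self.sex_offset, dtype=float)
            object.__setattr__(self, "sex_offset", so)
            if so.shape != t.shape:
                problems.append(f"sex_offset shape {so.shape} != template {t.shape}")
        if self.mean_displacement is not None:
            md = np.asarray(self.mean_displacement, dtype=float)
            object.__setattr__(self, "mean_displacement", md)
            if md.shape != t.shape:
                problems.append(f"mean_displacement shape {md.shape} != template {t.shape}")
        if problems:
            raise ValueError("invalid SimulationSpec: " + "; ".join(problems))
        object.__setattr__(self, "effects", tuple(self.effects))
        object.__setattr__(self, "landmark_names", tuple(self.landmark_names))


def _random_rotation(rng: np.random.Generator, d: int) -> np.ndarray:
    if d == 3:
        return Rotation.random(rng=rng).as_matrix()
    theta = rng.uniform(0.0, 2.0 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def simulate_population(spec: SimulationSpec, id_prefix: str | None = None) -> LandmarkDataset:
    """Draw one population of raw landmark configurations from a spec.

    One seed stream per dataset, split deterministically across specimens
    (child i depends only on the spec seed and i, so growing ``n`` preserves
    earlier specimens).  Metadata records sex, group and every latent
    predictor on its analysis scale.
    """
    k, d = spec.template.shape
    prefix = id_prefix if id_prefix is not None else f"{spec.group}_"
    children = np.random.SeedSequence(spec.seed).spawn(spec.n)
    configs = []
    meta_rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sex = "M" if rng.random() < spec.male_fraction else "F"
        shape = spec.template.copy()
        latents = {}
        scale = spec.base_scale
        for e in spec.effects:
            x = rng.normal(e.mean, e.sd)
            latents[e.name] = x
            shape = shape + e.slope * (x - e.anchor) * e.vector
            if e.sets_scale:
                scale = float(np.exp(x))
        if spec.sex_offset is not None and sex == "M":
            shape = shape + spec.sex_offset
        if spec.mean_displacement is not None:
            shape = shape + spec.mean_displacement
        shape = shape + rng.normal(0.0, spec.noise_sd, (k, d))
        if spec.rotate:
            R = _random_rotation(rng, d)
            shape = shape @ R.T
        if spec.scale_jitter > 0:
            scale = scale * float(np.exp(rng.normal(0.0, spec.scale_jitter)))
        t = rng.uniform(-spec.translation, spec.translation, d)
        raw = scale * shape + t
        sid = f"{prefix}{i + 1:03d}"
        configs.append(LandmarkConfiguration(sid, raw, spec.landmark_names))
        meta_rows.append({"specimen_id": sid, "sex": sex, "group": spec.group} | latents)
    return LandmarkDataset(configs, pd.DataFrame(meta_rows))


def simulate_mutant_pair(
    spec: SimulationSpec,
    n_mutant: int,
    predictor: str | None = None,
    delta: float | None = None,
    displacement: np.ndarray | None = None,
    mutant_label: str = "mutant",
) -> LandmarkDataset:
    """A wildtype group drawn from ``spec`` plus a perturbed mutant group.

    Exactly one perturbation mode: either ``predictor``/``delta`` (the named
    latent's sampling mean shifts by ``delta`` on the analysis scale and the
    shape follows through the effect vector — and through the specimen scale
    for a ``sets_scale`` predictor), or ``displacement`` (a direct k x d mean
    shape offset).
    """
    shift_mode = predictor is not None or delta is not None
    if shift_mode and displacement is not None:
        raise ValueError("specify either a predictor shift or a displacement, not both")
    if not shift_mode and displacement is None:
        raise ValueError("one of predictor shift or displacement is required")
    if shift_mode and (predictor is None or delta is None):
        raise ValueError("predictor shift needs both predictor and delta")

    wt = simulate_population(spec)

    mut_seed = int(np.random.SeedSequence([spec.seed, 1]).generate_state(1)[0] % (2**31))
    changes: dict = {"n": n_mutant, "seed": mut_seed, "group": mutant_label}
    if shift_mode:
        names = [e.name for e in spec.effects]
        if predictor not in names:
            raise ValueError(f"no effect named {predictor!r}; available: {names}")
        new_effects = tuple(
            replace(e, mean=e.mean + delta, ref_mean=e.anchor) if e.name == predictor else e
            for e in spec.effects
        )
        changes["effects"] = new_effects
    else:
        changes["mean_displacement"] = displacement
    mut = simulate_population(replace(spec, **changes))

    meta = pd.concat([wt.metadata, mut.metadata], ignore_index=True)
    return LandmarkDataset(wt.configurations + mut.configurations, meta)


def measure_predictors(
    dataset: LandmarkDataset,
    hormion: str = "hormion",
    opisthocranion: str = "opisthocranion",
) -> LandmarkDataset:
    """Append measured predictors to the metadata table.

    ``chondrocranial_length`` — hormion–opisthocranion distance in raw (mm)
    coordinates; ``overall_size`` — natural-log centroid size.  Brain size
    has no landmark proxy and stays whatever latent/measured column the
    metadata already carries (cube-root scale by convention).
    """
    for lm in (hormion, opisthocranion):
        if lm not in dataset.landmark_names:
            raise KeyError(
                f"landmark {lm!r} not in dataset; available: {list(dataset.landmark_names)}"
            )
    chond = [
        interlandmark_distance(c, hormion, opisthocranion)
        for c in dataset.configurations
    ]
    logcs = [float(np.log(centroid_size(c))) for c in dataset.configurations]
    meta = dataset.metadata.copy()
    meta["chondrocranial_length"] = chond
    meta["overall_size"] = logcs
    return dataclasses.replace(dataset, metadata=meta)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: per-coordinate tangent-space noise SD; with 3*18-7 = 47 effective shape
#: dimensions this puts the three predictors' variance fractions in the
#: observed wildtype-mouse range (a few percent each; derivation in the docs)
DEFAULT_NOISE_SD = 0.006

_TEMPLATE_CHONDRO_MM = 30.0 * float(
    np.linalg.norm(TEMPLATE[_IDX["hormion"]] - TEMPLATE[_IDX["opisthocranion"]])
)

_MOUSE_PREDICTORS = {
    # name: (mean, cv, slope) on the analysis scale
    "brain_size": (7.66, 0.048, 0.0261),                      # cube-root volume, mm
    "chondro_length": (_TEMPLATE_CHONDRO_MM, 0.024, 0.0519),  # hormion-opisthocranion, mm
    "log_centroid_size": (np.log(30.0), 0.017, 0.2389),       # log mm
}
_SEX_OFFSET_NORM = 0.0081


def mouse_study_spec(seed: int, n: int = 48, noise_sd: float = DEFAULT_NOISE_SD) -> SimulationSpec:
    """Spec emulating a wildtype mouse sample.

    Predictor coefficients of variation (0.048, 0.024, 0.017), the sample
    size (48) and variance fractions of a few percent per predictor follow
    the wildtype-mouse regime the pipeline is designed for; the overall-size
    latent also sets the specimen's raw scale, so log centroid size is a
    measured quantity, not a passthrough.
    """
    effects = tuple(
        EffectSpec(
            name=name,
            vector=_DEFAULT_VECTORS[name if name != "chondro_length" else "chondro_length"],
            slope=slope,
            mean=mean,
            sd=cv * mean,
            sets_scale=(name == "log_centroid_size"),
        )
        for name, (mean, cv, slope) in _MOUSE_PREDICTORS.items()
    )
    return SimulationSpec(
        n=n,
        seed=seed,
        effects=effects,
        sex_offset=_SEX_OFFSET_NORM * _DEFAULT_VECTORS["sex"],
        noise_sd=noise_sd,
    )
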