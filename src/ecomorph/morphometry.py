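"""Geometric and linear morphometrics: from raw landmarks and bone
measurements to the scaled trait matrix all downstream analyses consume.

The trait space is built in five steps: (1) right-side landmark
configurations are mirrored onto the left, (2) each girdle's landmark set
is superimposed by generalized Procrustes analysis (GPA), (3) missing
linear measurements are imputed by iterative PCA, (4) lengths and
thicknesses are divided by pelvic centroid size (the body-size proxy),
and (5) every column is transformed to standard normal deviates so that
shape and univariate traits live on a commensurate scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_LANDMARKS = 18
STRUCTURES = ("pectoral", "pelvic")
SIDES = ("left", "right")
AXES = {"x": 0, "y": 1, "z": 2}

#: canonical composition of the trait matrix
TRAIT_BLOCKS = (("shape", 54), ("shape", 54), ("length", 15), ("thickness", 8), ("size", 1))
N_TRAITS = 132


@dataclass
class LandmarkConfiguration:
    """One structure's 18 named 3D landmarks for one specimen (mm)."""

    structure: str
    side: str
    coords: np.ndarray

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 3):
            raise ValueError(
                f"expected {N_LANDMARKS} landmarks x 3 coordinates, got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")


def mirror_configuration(config: LandmarkConfiguration, axis: str = "x") -> LandmarkConfiguration:
    """Reflect a configuration across one coordinate plane.

    Used to bring right-side girdles onto the left side before GPA, since
    the superimposition is rotation-only (no reflections). Applying the
    mirror twice returns the input exactly.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    coords = config.coords.copy()
    coords[:, AXES[axis]] *= -1.0
    side = "left" if config.side == "right" else "right"
    return LandmarkConfiguration(structure=config.structure, side=side, coords=coords)


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


@dataclass
class GPAResult:
    aligned: np.ndarray          # n x 18 x 3 Procrustes shape variables
    centroid_sizes: np.ndarray   # n, in mm
    mean_shape: np.ndarray       # 18 x 3
    iterations: int
    converged: bool


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation-only (det=+1) orthogonal Procrustes solution (Kabsch)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.ones(u.shape[1])
    correction[-1] = d
    return (u * correction) @ vt


def gpa(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> GPAResult:
    """Generalized Procrustes superimposition of same-structure configurations.

    Each configuration is translated to centroid origin and scaled to unit
    centroid size, then iteratively rotated (rotation-only) onto the
    evolving mean shape until the mean stabilizes. No tangent-space
    projection and no dimension reduction: the redundant degrees of
    freedom are retained and analyses proceed on the raw Procrustes
    shape variables.
    """
    if len(configs) == 0:
        raise ValueError("need at least one configuration")
    structures = {c.structure for c in configs}
    if len(structures) > 1:
        raise ValueError(f"configurations mix structures: {sorted(structures)}")
    if any(c.side != "left" for c in configs):
        raise ValueError("all configurations must be left-side; mirror right-side ones first")

    n = len(configs)
    shapes = np.empty((n, N_LANDMARKS, 3))
    sizes = np.empty(n)
    for i, c in enumerate(configs):
        centered = c.coords - c.coords.mean(axis=0)
        cs = np.sqrt(np.sum(centered**2))
        if cs <= 0:
            raise ValueError(f"degenerate configuration at index {i}: zero centroid size")
        shapes[i] = centered / cs
        sizes[i] = cs

    mean = shapes[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], mean)
        new_mean = shapes.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        nm_size = np.sqrt(np.sum(new_mean**2))
        if nm_size > 0:
            new_mean /= nm_size
        # align new mean to old so the convergence distance is rotation-free
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        change = np.sqrt(np.sum((new_mean - mean) ** 2))
        mean = new_mean
        if change < tol:
            converged = True
            break

    return GPAResult(
        aligned=shapes,
        centroid_sizes=sizes,
        mean_shape=shapes.mean(axis=0),
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-sum-square coordinate distance between two aligned shapes."""
    return float(np.sqrt(np.sum((np.asarray(a) - np.asarray(b)) ** 2)))


# ---------------------------------------------------------------------------
# linear measurements


def impute_missing(
    linear: pd.DataFrame,
    q: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Complete missing cells of a measurement table by iterative PCA.

    Missing cells start at their column mean; the table is then
    alternately reconstructed at rank ``q`` (SVD of the column-centered
    matrix) and the missing cells replaced by the reconstruction, until
    the largest cell change falls below ``tol``. Observed cells are never
    altered.
    """
    values = linear.to_numpy(dtype=float, copy=True)
    mask = np.isnan(values)
    if not mask.any():
        return linear.copy()
    if mask.all(axis=0).any():
        bad = list(linear.columns[mask.all(axis=0)])
        raise ValueError(f"columns entirely missing: {bad}")
    if mask.all(axis=1).any():
        bad = list(linear.index[mask.all(axis=1)])
        raise ValueError(f"rows entirely missing: {bad}")
    frac = mask.mean()
    if frac > 0.10:
        warnings.warn(f"missing fraction {frac:.1%} exceeds 10%; imputation may be unreliable")

    col_means = np.nanmean(values, axis=0)
    values[mask] = np.take(col_means, np.where(mask)[1])
    q = min(q, min(values.shape) - 1) if min(values.shape) > 1 else 1
    for _ in range(max_iter):
        mu = values.mean(axis=0)
        centered = values - mu
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        recon = mu + (u[:, :q] * s[:q]) @ vt[:q]
        change = np.max(np.abs(recon[mask] - values[mask]))
        values[mask] = recon[mask]
        if change < tol:
            break
    return pd.DataFrame(values, index=linear.index, columns=linear.columns)


def size_correct(linear: pd.DataFrame, sizes: pd.Series | np.ndarray) -> pd.DataFrame:
    """Divide every specimen's measurements by its pelvic centroid size."""
    sizes = np.asarray(pd.Series(sizes).reindex(linear.index) if isinstance(sizes, pd.Series) else sizes, float)
    if sizes.shape[0] != linear.shape[0]:
        raise ValueError("sizes not aligned to rows")
    if np.any(~np.isfinite(sizes)) or np.any(sizes <= 0):
        raise ValueError("centroid sizes must be strictly positive and finite")
    return linear.div(sizes, axis=0)


# ---------------------------------------------------------------------------
# trait matrix


def classify_columns(names) -> pd.Series:
    """Map trait column names to their class by prefix convention."""
    out = {}
    for name in names:
        if name.startswith(("shape_pec_", "shape_pel_")):
            out[name] = "shape"
        elif name.startswith("len_"):
            out[name] = "length"
        elif name.startswith("thick_"):
            out[name] = "thickness"
        elif name.startswith("size"):
            out[name] = "size"
        else:
            raise ValueError(f"cannot classify trait column {name!r}")
    return pd.Series(out)


@dataclass
class TraitMatrix:
    """Specimens x traits on the standard-normal-deviate scale.

    ``scaling_record`` holds the per-column (mean, sd) of the scaling
    population, so new rows can be projected onto an existing scale.
    """

    values: pd.DataFrame
    column_class: pd.Series
    scaling_record: pd.DataFrame = field(repr=False)

    @property
    def columns(self):
        return self.values.columns

    def project(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Scale new raw rows using the stored scaling population."""
        rec = self.scaling_record.loc[raw.columns]
        return (raw - rec["mean"]) / rec["sd"]


def standardize(raw: pd.DataFrame, column_class: pd.Series | None = None) -> TraitMatrix:
    """Transform each trait column to standard normal deviates.

    Centering and scaling use the sample standard deviation (n-1). A
    constant column cannot be scaled and raises, naming the column.
    """
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    bad = list(raw.columns[(sds == 0) | ~np.isfinite(sds)])
    if bad:
        raise ValueError(f"constant or degenerate columns cannot be standardized: {bad}")
    values = (raw - means) / sds
    if column_class is None:
        column_class = classify_columns(raw.columns)
    record = pd.DataFrame({"mean": means, "sd": sds})
    return TraitMatrix(values=values, column_class=column_class, scaling_record=record)


def _shape_frame(result: GPAResult, ids, prefix: str) -> pd.DataFrame:
    cols = [f"{prefix}L{l+1}_{ax}" for l in range(N_LANDMARKS) for ax in ("x", "y", "z")]
    return pd.DataFrame(result.aligned.reshape(len(ids), -1), index=list(ids), columns=cols)


def assemble_traits(
    gpa_pec: GPAResult,
    pec_ids,
    gpa_pel: GPAResult,
    pel_ids,
    corrected_linear: pd.DataFrame,
    size_name: str = "size_pelvic_cs",
) -> pd.DataFrame:
    """Assemble the raw 132-column trait table in canonical order.

    Columns: 54 pectoral shape, 54 pelvic shape, 15 lengths, 8
    thicknesses, 1 body-size proxy (pelvic centroid size). Specimens
    lacking either girdle are excluded with a warning; specimens present
    in both girdles but absent from the linear table are an error. The
    result is raw-scale; apply :func:`standardize` over the analysis
    population last.
    """
    pec = _shape_frame(gpa_pec, pec_ids, "shape_pec_")
    pel = _shape_frame(gpa_pel, pel_ids, "shape_pel_")
    common = pec.index.intersection(pel.index)
    dropped = pec.index.symmetric_difference(pel.index)
    if len(dropped):
        warnings.warn(f"excluding {len(dropped)} specimens lacking one girdle: {sorted(dropped)[:5]}...")
    missing = set(common) - set(corrected_linear.index)
    extra = set(corrected_linear.index) - set(common)
    if missing:
        raise ValueError(
            f"specimen sets mismatch: missing from linear table {sorted(missing)}; "
            f"only in linear table {sorted(extra)}"
        )
    sizes = pd.Series(gpa_pel.centroid_sizes, index=list(pel_ids), name=size_name)
    out = pd.concat(
        [pec.loc[common], pel.loc[common], corrected_linear.loc[common], sizes.loc[common]],
        axis=1,
    )
    return out


# ---------------------------------------------------------------------------
# repeatability


@dataclass
class RepeatabilityResult:
    structure: str
    R: float
    ms_among: float
    ms_within: float
    n_individuals: int
    n_replicates: float


def repeatability(replicates: dict[str, list[LandmarkConfiguration]]) -> RepeatabilityResult:
    """Intraclass correlation of the landmarking procedure.

    All replicate configurations are superimposed together by GPA; a
    Procrustes one-way ANOVA on the aligned coordinates (sums of squared
    deviations pooled over all landmarks and axes, individual as the
    grouping factor) yields mean squares, and R = s2_A / (s2_A + MS_within)
    with s2_A = (MS_among - MS_within) / k0. Unbalanced designs use the
    standard ICC correction k0 = (N - sum(k_i^2)/N) / (n - 1).
    """
    individuals = sorted(replicates)
    if len(individuals) < 2:
        raise ValueError("need at least two individuals")
    counts = {ind: len(replicates[ind]) for ind in individuals}
    if any(k < 2 for k in counts.values()):
        raise ValueError("each individual needs at least two replicate configurations")

    configs, labels = [], []
    for ind in individuals:
        for c in replicates[ind]:
            configs.append(c)
            labels.append(ind)
    structure = configs[0].structure
    res = gpa(configs)
    flat = res.aligned.reshape(len(configs), -1)
    labels = np.asarray(labels)

    grand = flat.mean(axis=0)
    ss_within = 0.0
    ss_among = 0.0
    for ind in individuals:
        rows = flat[labels == ind]
        center = rows.mean(axis=0)
        ss_within += float(np.sum((rows - center) ** 2))
        ss_among += counts[ind] * float(np.sum((center - grand) ** 2))
    n = len(individuals)
    total = sum(counts.values())
    ms_among = ss_among / (n - 1)
    ms_within = ss_within / (total - n)
    k0 = (total - sum(k * k for k in counts.values()) / total) / (n - 1)
    if ms_within == 0:
        r = 1.0
    else:
        s2a = max((ms_among - ms_within) / k0, 0.0)
        r = s2a / (s2a + ms_within)
    return RepeatabilityResult(
        structure=structure,
        R=float(min(max(r, 0.0), 1.0)),
        ms_among=ms_among,
        ms_within=ms_within,
        n_individuals=n,
        n_replicates=k0,
    )


# ---------------------------------------------------------------------------
# variance structure


@dataclass
class PCASummary:
    variance_fractions: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray


def pca_variance(
    traits: TraitMatrix | pd.DataFrame,
    level: str = "individual",
    species: pd.Series | None = None,
) -> PCASummary:
    """Principal components of the (already scaled) trait matrix.

    ``level='species-mean'`` averages rows per species before the
    eigendecomposition. At most min(n-1, m) components are returned.
    """
    values = traits.values if isinstance(traits, TraitMatrix) else traits
    if level == "species-mean":
        if species is None:
            raise ValueError("species mapping required at species-mean level")
        values = values.groupby(pd.Series(species).reindex(values.index)).mean()
    elif level != "individual":
        raise ValueError(f"unknown level {level!r}")
    x = values.to_numpy(dtype=float)
    n, m = x.shape
    if n <= 2:
        raise ValueError("need more than two rows")
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n - 1, m)
    var = s[:k] ** 2
    return PCASummary(
        variance_fractions=var / var.sum(),
        scores=(u[:, :k] * s[:k]),
        loadings=vt[:k].T,
    )
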