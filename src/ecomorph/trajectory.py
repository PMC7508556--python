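"""Phenotypic trajectory analysis of parallel divergence.

For a pair of ecomorphs on one island, the divergence trajectory is a
vector of per-trait two-sample t-values (mean difference in units of its
standard error). Comparing the same ecomorph contrast across two islands
("a quartet") yields the angle theta between the two trajectories
(0 deg = perfectly parallel divergence, 90 deg = unrelated directions)
and delta-L, the difference of their lengths. Significance is assessed
by permuting island labels (parallel null) and bootstrapping specimens
(test against orthogonality).
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrajectoryVector:
    """Per-trait divergence statistics for one group contrast (A - B)."""

    t_values: np.ndarray
    contrast: tuple[str, str]
    n_a: int
    n_b: int
    method: str = "t_statistic"
    columns: object = None

    @property
    def L(self) -> float:
        """Euclidean length of the trajectory vector."""
        return float(np.sqrt(np.sum(self.t_values**2)))


def _t_stats(a: np.ndarray, b: np.ndarray, variant: str) -> np.ndarray:
    """Columnwise two-sample t statistics, vectorized over traits."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if variant == "welch":
        denom = np.sqrt(va / na + vb / nb)
    elif variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        raise ValueError(f"unknown t variant {variant!r}")
    t = np.zeros_like(denom)
    ok = denom > 0
    t[ok] = (ma - mb)[ok] / denom[ok]
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} traits had zero variance in a contrast; t set to 0")
    return t


def t_vector(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    contrast: tuple[str, str] = ("A", "B"),
    variant: str = "welch",
) -> TrajectoryVector:
    """Trajectory vector of per-trait two-sample t-values (A - B sign)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need at least two specimens for t-values")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different trait columns")
    cols = group_a.columns if isinstance(group_a, pd.DataFrame) else None
    return TrajectoryVector(
        t_values=_t_stats(a, b, variant),
        contrast=contrast,
        n_a=a.shape[0],
        n_b=b.shape[0],
        method="t_statistic",
        columns=cols,
    )


def mean_difference_vector(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    contrast: tuple[str, str] = ("A", "B"),
) -> TrajectoryVector:
    """Phenotypic change vector of multivariate mean differences (A - B)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("both groups need at least one specimen")
    cols = group_a.columns if isinstance(group_a, pd.DataFrame) else None
    return TrajectoryVector(
        t_values=a.mean(axis=0) - b.mean(axis=0),
        contrast=contrast,
        n_a=a.shape[0],
        n_b=b.shape[0],
        method="mean_difference",
        columns=cols,
    )


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na = np.sqrt(np.sum(a**2))
    nb = np.sqrt(np.sum(b**2))
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero-length vector")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def vector_angle(a: TrajectoryVector | np.ndarray, b: TrajectoryVector | np.ndarray) -> float:
    """Angle theta (degrees, in [0, 180]) between two trajectory vectors."""
    va = a.t_values if isinstance(a, TrajectoryVector) else np.asarray(a, float)
    vb = b.t_values if isinstance(b, TrajectoryVector) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError("vectors have different dimensions")
    return _angle_deg(va, vb)


def delta_length(a: TrajectoryVector | np.ndarray, b: TrajectoryVector | np.ndarray) -> float:
    """Difference of trajectory lengths, L(a) - L(b)."""
    la = a.L if isinstance(a, TrajectoryVector) else float(np.sqrt(np.sum(np.asarray(a, float) ** 2)))
    lb = b.L if isinstance(b, TrajectoryVector) else float(np.sqrt(np.sum(np.asarray(b, float) ** 2)))
    return la - lb


# ---------------------------------------------------------------------------
# quartets


@dataclass
class QuartetComparison:
    """One ecomorph pair contrasted on one island pair."""

    ecomorphs: tuple[str, str]
    islands: tuple[str, str]

    @property
    def label(self) -> str:
        return f"{self.ecomorphs[0]}|{self.ecomorphs[1]}|{self.islands[0]}|{self.islands[1]}"


def enumerate_quartets(metadata: pd.DataFrame, min_n: int = 2) -> list[QuartetComparison]:
    """All ecomorph-pair x island-pair combinations with usable samples.

    A quartet is retained when both ecomorphs have at least ``min_n``
    specimens on both islands. Ordering is deterministic: ecomorph pairs
    then island pairs, lexicographic.
    """
    counts = (
        metadata.dropna(subset=["island", "ecomorph"])
        .groupby(["ecomorph", "island"], observed=True)
        .size()
    )

    def n_of(eco, isl):
        return int(counts.get((eco, isl), 0))

    ecos = sorted(metadata["ecomorph"].dropna().unique())
    isls = sorted(metadata["island"].dropna().unique())
    out = []
    for e1, e2 in itertools.combinations(ecos, 2):
        for i1, i2 in itertools.combinations(isls, 2):
            if all(n_of(e, i) >= min_n for e in (e1, e2) for i in (i1, i2)):
                out.append(QuartetComparison(ecomorphs=(e1, e2), islands=(i1, i2)))
    return out


def _cell_indices(metadata: pd.DataFrame, quartet: QuartetComparison, index: pd.Index):
    """Positional indices of the four ecomorph x island cells in ``index``."""
    pos = {sid: i for i, sid in enumerate(index)}
    cells = {}
    for e in quartet.ecomorphs:
        for i in quartet.islands:
            sel = metadata[(metadata["ecomorph"] == e) & (metadata["island"] == i)].index
            cells[(e, i)] = np.array([pos[s] for s in sel if s in pos], dtype=int)
    return cells


def quartet_vectors(
    quartet: QuartetComparison,
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    method: str = "t_statistic",
    variant: str = "welch",
) -> tuple[TrajectoryVector, TrajectoryVector]:
    """The two island trajectory vectors (e1 - e2 on each island)."""
    x = traits.to_numpy(dtype=float)
    cells = _cell_indices(metadata, quartet, traits.index)
    e1, e2 = quartet.ecomorphs
    make = t_vector if method == "t_statistic" else mean_difference_vector
    kwargs = {"variant": variant} if method == "t_statistic" else {}
    vs = []
    for isl in quartet.islands:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vs.append(
                make(
                    pd.DataFrame(x[cells[(e1, isl)]], columns=traits.columns),
                    pd.DataFrame(x[cells[(e2, isl)]], columns=traits.columns),
                    contrast=(e1, e2),
                    **kwargs,
                )
            )
    return vs[0], vs[1]


@dataclass
class AngleTestResult:
    quartet: QuartetComparison
    theta: float
    delta_L: float
    p_parallel: float
    p_length: float
    p_orthogonal: float
    n_perm: int
    n_boot: int
    seed: int
    classification: str = ""


def _quartet_theta_dl(x, cells, e1, e2, i1, i2, variant):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v1 = _t_stats(x[cells[(e1, i1)]], x[cells[(e2, i1)]], variant)
        v2 = _t_stats(x[cells[(e1, i2)]], x[cells[(e2, i2)]], variant)
    return _angle_deg(v1, v2), float(np.sqrt(np.sum(v1**2)) - np.sqrt(np.sum(v2**2)))


def permutation_parallel_test(
    quartet: QuartetComparison,
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    variant: str = "welch",
    scheme: str = "within_ecomorph",
) -> tuple[float, float]:
    """Permutation test of parallelism for one quartet.

    Island labels are shuffled among each ecomorph's specimens (cell
    sizes preserved), simulating parallel divergence; the null
    distributions of theta and |delta-L| are compared against the
    observed values. Small p means the observed trajectories are
    significantly less parallel (or more length-divergent) than the
    parallel null. ``scheme='pooled'`` instead shuffles islands across
    the whole quartet.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = traits.to_numpy(dtype=float)
    cells = _cell_indices(metadata, quartet, traits.index)
    if any(len(v) < 2 for v in cells.values()):
        raise ValueError(f"quartet {quartet.label}: every cell needs >= 2 specimens to permute")
    e1, e2 = quartet.ecomorphs
    i1, i2 = quartet.islands
    obs_theta, obs_dl = _quartet_theta_dl(x, cells, e1, e2, i1, i2, variant)

    rng = np.random.default_rng(seed)
    ge_theta = 0
    ge_dl = 0
    for _ in range(n_perm):
        perm_cells = {}
        if scheme == "within_ecomorph":
            for e in (e1, e2):
                pool = np.concatenate([cells[(e, i1)], cells[(e, i2)]])
                rng.shuffle(pool)
                perm_cells[(e, i1)] = pool[: len(cells[(e, i1)])]
                perm_cells[(e, i2)] = pool[len(cells[(e, i1)]):]
        elif scheme == "pooled":
            pool = np.concatenate([cells[c] for c in cells])
            rng.shuffle(pool)
            off = 0
            for c in cells:
                perm_cells[c] = pool[off: off + len(cells[c])]
                off += len(cells[c])
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        th, dl = _quartet_theta_dl(x, perm_cells, e1, e2, i1, i2, variant)
        ge_theta += th >= obs_theta
        ge_dl += abs(dl) >= abs(obs_dl)
    p_parallel = (ge_theta + 1) / (n_perm + 1)
    p_length = (ge_dl + 1) / (n_perm + 1)
    return p_parallel, p_length


def bootstrap_orthogonality_test(
    quartet: QuartetComparison,
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    n_boot: int = 999,
    seed: int = 0,
    variant: str = "welch",
) -> float:
    """Bootstrap test of theta against orthogonality (90 degrees).

    Specimens are resampled with replacement within each ecomorph x
    island cell; theta is recomputed per replicate. The p-value is the
    smoothed fraction of bootstrap angles at or beyond 90 degrees: small
    p rejects orthogonal divergence directions.
    """
    if n_boot < 99:
        raise ValueError("n_boot must be at least 99")
    x = traits.to_numpy(dtype=float)
    cells = _cell_indices(metadata, quartet, traits.index)
    if any(len(v) < 2 for v in cells.values()):
        warnings.warn(f"quartet {quartet.label}: cell of size < 2, bootstrap is degenerate")
    e1, e2 = quartet.ecomorphs
    i1, i2 = quartet.islands
    rng = np.random.default_rng(seed)
    ge_90 = 0
    for _ in range(n_boot):
        boot_cells = {c: rng.choice(v, size=len(v), replace=True) for c, v in cells.items()}
        try:
            th, _ = _quartet_theta_dl(x, boot_cells, e1, e2, i1, i2, variant)
        except ValueError:  # zero-length resampled vector; count as uninformative
            th = 90.0
        ge_90 += th >= 90.0
    return (ge_90 + 1) / (n_boot + 1)


def classify_quartet(p_parallel: float, p_orthogonal: float, alpha: float = 0.05) -> str:
    """Assign the angle-classification label from the two test p-values.

    Failure to reject the parallel null means the angle is
    indistinguishable from 0 degrees; failure to reject orthogonality
    means indistinguishable from 90; rejecting both places it in
    between. Rejecting neither is flagged ambiguous with a warning.
    """
    par_ok = p_parallel >= alpha        # parallel null not rejected
    orth_ok = p_orthogonal >= alpha     # orthogonal null not rejected
    if par_ok and not orth_ok:
        return "indistinguishable_from_0"
    if orth_ok and not par_ok:
        return "indistinguishable_from_90"
    if not par_ok and not orth_ok:
        return "between_0_and_90"
    warnings.warn("neither parallelism nor orthogonality rejected; quartet is ambiguous")
    return "ambiguous"


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-quartet seed derived from a master seed and a label."""
    return (int(master_seed) ^ zlib.crc32(label.encode())) % (2**31 - 1)


def analyze_quartet(
    quartet: QuartetComparison,
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = 999,
    n_boot: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    variant: str = "welch",
) -> AngleTestResult:
    """Observed theta / delta-L plus both significance tests for one quartet."""
    v1, v2 = quartet_vectors(quartet, traits, metadata, variant=variant)
    theta = vector_angle(v1, v2)
    dl = delta_length(v1, v2)
    p_par, p_len = permutation_parallel_test(
        quartet, traits, metadata, n_perm=n_perm, seed=seed, variant=variant
    )
    p_orth = bootstrap_orthogonality_test(
        quartet, traits, metadata, n_boot=n_boot, seed=seed + 1, variant=variant
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        label = classify_quartet(p_par, p_orth, alpha=alpha)
    return AngleTestResult(
        quartet=quartet,
        theta=theta,
        delta_L=dl,
        p_parallel=p_par,
        p_length=p_len,
        p_orthogonal=p_orth,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        classification=label,
    )


# ---------------------------------------------------------------------------
# outlier-based trait ranking


@dataclass
class OutlierScan:
    z_scores: np.ndarray
    flagged: set
    prob: float
    columns: object = None


def outlier_traits(v: TrajectoryVector, prob: float = 0.95) -> OutlierScan:
    """Flag traits whose t-values are outliers within the vector itself.

    Each trait's t-value is z-scored against the distribution of all
    vector elements; traits beyond the two-sided normal quantile at
    ``prob`` (default: outside the 95th percentile in either direction)
    are flagged as the contrast's signature traits ("most divergent" or
    "most plastic" sets).
    """
    t = np.asarray(v.t_values, dtype=float)
    sd = t.std(ddof=1)
    if sd == 0:
        raise ValueError("t-values are constant; outlier scan undefined")
    z = (t - t.mean()) / sd
    cut = stats.norm.ppf(prob)
    idx = np.where(np.abs(z) > cut)[0]
    cols = list(v.columns) if v.columns is not None else list(range(len(t)))
    return OutlierScan(z_scores=z, flagged={cols[i] for i in idx}, prob=prob, columns=cols)


def angle_method_correlation(
    quartets: list[QuartetComparison],
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    variant: str = "welch",
) -> float:
    """Pearson correlation of per-quartet theta across the two methods.

    Cross-validates the t-statistic trajectories against phenotypic
    change vectors built from multivariate mean differences.
    """
    if len(quartets) < 3:
        raise ValueError("need at least three quartets")
    th_t, th_m = [], []
    for q in quartets:
        v1, v2 = quartet_vectors(q, traits, metadata, method="t_statistic", variant=variant)
        w1, w2 = quartet_vectors(q, traits, metadata, method="mean_difference")
        th_t.append(vector_angle(v1, v2))
        th_m.append(vector_angle(w1, w2))
    return float(stats.pearsonr(th_t, th_m)[0])
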