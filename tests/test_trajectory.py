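"""Trajectory vectors, angles, permutation/bootstrap tests, outlier scans."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ecomorph as em
from ecomorph.trajectory import derive_seed, quartet_vectors


def _frame(rows, cols=1):
    return pd.DataFrame(np.atleast_2d(np.asarray(rows, float)).reshape(len(rows), -1))


def test_t_vector_identical_groups_is_zero():
    a = _frame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    v = em.t_vector(a, a.copy())
    assert np.allclose(v.t_values, 0)
    assert v.L == 0


def test_t_vector_pooled_hand_value():
    # A={0,1,2}, B={3,4,5}: mean diff -3, pooled sd 1, se sqrt(2/3)
    a = _frame([[0.0], [1.0], [2.0]])
    b = _frame([[3.0], [4.0], [5.0]])
    v = em.t_vector(a, b, variant="pooled")
    assert v.t_values[0] == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-3)
    assert v.t_values[0] == pytest.approx(-3.674, abs=1e-3)
    # equal group sizes: Welch coincides with pooled
    w = em.t_vector(a, b, variant="welch")
    assert w.t_values[0] == pytest.approx(v.t_values[0])


def test_t_vector_sign_equivariance(rng):
    a = pd.DataFrame(rng.normal(size=(5, 3)))
    b = pd.DataFrame(rng.normal(1.0, 1.0, size=(6, 3)))
    v = em.t_vector(a, b)
    a2, b2 = a.copy(), b.copy()
    a2[1] *= -1
    b2[1] *= -1
    v2 = em.t_vector(a2, b2)
    assert v2.t_values[1] == pytest.approx(-v.t_values[1])
    assert v2.t_values[0] == pytest.approx(v.t_values[0])
    assert v2.t_values[2] == pytest.approx(v.t_values[2])


def test_t_vector_zero_variance_trait_warns():
    a = _frame([[1.0, 5.0], [1.0, 6.0]])
    b = _frame([[1.0, 9.0], [1.0, 7.0]])
    with pytest.warns(UserWarning, match="zero variance"):
        v = em.t_vector(a, b)
    assert v.t_values[0] == 0


def test_mean_difference_vector():
    a = _frame([[1.0, 0.0]])
    b = _frame([[0.0, 0.0]])
    v = em.mean_difference_vector(a, b)
    assert np.allclose(v.t_values, [1, 0])
    assert v.L == pytest.approx(1.0)
    assert v.method == "mean_difference"


def test_vector_angle_closed_forms():
    e1 = np.zeros(132); e1[0] = 1
    e2 = np.zeros(132); e2[1] = 1
    assert em.vector_angle(e1, e1) == pytest.approx(0.0)
    assert em.vector_angle(e1, e2) == pytest.approx(90.0)
    assert em.vector_angle(np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])) == pytest.approx(45.0)
    assert em.vector_angle(e1, -e1) == pytest.approx(180.0)
    assert em.vector_angle(e1, 3.7 * e1) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="zero-length"):
        em.vector_angle(e1, np.zeros(132))


def test_delta_length_antisymmetry():
    a = np.array([3.0, 4.0])
    b = np.array([0.0, 1.0])
    assert em.delta_length(a, b) == pytest.approx(4.0)
    assert em.delta_length(a, a) == 0.0
    assert em.delta_length(b, a) == pytest.approx(-em.delta_length(a, b))


def test_random_vectors_average_ninety_degrees(rng):
    """Independent standard-normal vectors are orthogonal on average."""
    angles = []
    for _ in range(2000):
        angles.append(em.vector_angle(rng.normal(size=132), rng.normal(size=132)))
    assert np.mean(angles) == pytest.approx(90.0, abs=0.5)


# quartets -----------------------------------------------------------------


def _meta(cells):
    """metadata frame from {(ecomorph, island): n} cell sizes."""
    rows = []
    i = 0
    for (eco, isl), n in cells.items():
        for _ in range(n):
            i += 1
            rows.append({"specimen_id": f"s{i}", "species": f"sp_{eco}_{isl}",
                         "island": isl, "ecomorph": eco, "sex": "male",
                         "source": "museum", "treatment": None})
    return pd.DataFrame(rows).set_index("specimen_id")


def test_enumerate_quartets_full_and_missing_cells():
    cells = {(e, i): 3 for e in ("e1", "e2", "e3") for i in ("i1", "i2")}
    meta = _meta(cells)
    qs = em.enumerate_quartets(meta)
    assert len(qs) == 3  # C(3,2) ecomorph pairs x C(2,2) island pair
    del cells[("e3", "i2")]
    qs2 = em.enumerate_quartets(_meta(cells))
    assert len(qs2) == 1
    assert qs2[0].ecomorphs == ("e1", "e2")


def test_enumerate_quartets_brute_force_oracle(rng):
    """Enumeration equals a brute-force scan over all pair combinations."""
    ecos = ["e1", "e2", "e3", "e4"]
    isls = ["i1", "i2", "i3"]
    cells = {}
    for e in ecos:
        for i in isls:
            n = int(rng.integers(0, 5))
            if n:
                cells[(e, i)] = n
    meta = _meta(cells)
    got = {(q.ecomorphs, q.islands) for q in em.enumerate_quartets(meta, min_n=2)}
    expected = set()
    for e1, e2 in itertools.combinations(sorted(ecos), 2):
        for i1, i2 in itertools.combinations(sorted(isls), 2):
            if all(cells.get((e, i), 0) >= 2 for e in (e1, e2) for i in (i1, i2)):
                expected.add(((e1, e2), (i1, i2)))
    assert got == expected


def test_paper_design_has_53_quartets(paper_design_radiation):
    qs = em.enumerate_quartets(paper_design_radiation.metadata)
    assert len(qs) == 53


def _parallel_dataset(seed, n_per_cell=8, m=132, effect=1.0, delta=0.0):
    """Two ecomorphs on two islands; delta=0 means exactly parallel."""
    rng = np.random.default_rng(seed)
    beta = {"e1": rng.normal(0, effect, m), "e2": rng.normal(0, effect, m)}
    cells = {}
    rows, ids = [], []
    meta_rows = []
    i = 0
    for eco in ("e1", "e2"):
        for isl in ("i1", "i2"):
            dev = delta * rng.normal(size=m)
            for _ in range(n_per_cell):
                i += 1
                ids.append(f"s{i}")
                rows.append(beta[eco] + dev + rng.normal(size=m))
                meta_rows.append({"specimen_id": f"s{i}", "species": f"{eco}{isl}",
                                  "island": isl, "ecomorph": eco, "sex": "male",
                                  "source": "museum", "treatment": None})
    traits = pd.DataFrame(rows, index=ids)
    meta = pd.DataFrame(meta_rows).set_index("specimen_id")
    return traits, meta


def test_permutation_test_deterministic_under_seed():
    traits, meta = _parallel_dataset(3)
    q = em.enumerate_quartets(meta)[0]
    p1 = em.permutation_parallel_test(q, traits, meta, n_perm=99, seed=42)
    p2 = em.permutation_parallel_test(q, traits, meta, n_perm=99, seed=42)
    assert p1 == p2
    p3 = em.permutation_parallel_test(q, traits, meta, n_perm=99, seed=43)
    assert p1 != p3  # different permutations, generically different p


def test_permutation_test_power_on_orthogonal_divergence(rng):
    """Islands given near-orthogonal strong divergence vectors: parallelism
    is rejected decisively."""
    m = 132
    u = np.zeros(m); u[:66] = 1.0
    v = np.zeros(m); v[66:] = 1.0
    rows, meta_rows = [], []
    i = 0
    for eco, sign in (("e1", 1.0), ("e2", -1.0)):
        for isl, vec in (("i1", u), ("i2", v)):
            for _ in range(15):
                i += 1
                rows.append(sign * 2.0 * vec + rng.normal(size=m))
                meta_rows.append({"specimen_id": f"s{i}", "species": f"{eco}{isl}",
                                  "island": isl, "ecomorph": eco, "sex": "male",
                                  "source": "museum", "treatment": None})
    traits = pd.DataFrame(rows, index=[r["specimen_id"] for r in meta_rows])
    meta = pd.DataFrame(meta_rows).set_index("specimen_id")
    q = em.enumerate_quartets(meta)[0]
    p_par, _ = em.permutation_parallel_test(q, traits, meta, n_perm=199, seed=5)
    assert p_par <= 0.01


def test_permutation_test_requires_permutable_cells():
    traits, meta = _parallel_dataset(9, n_per_cell=1)
    q = em.QuartetComparison(("e1", "e2"), ("i1", "i2"))
    with pytest.raises(ValueError, match=">= 2"):
        em.permutation_parallel_test(q, traits, meta, n_perm=99, seed=0)


def test_bootstrap_orthogonality_detects_small_angle(rng):
    """Aligned strong divergence on both islands: bootstrap mass is far
    below 90 degrees, so orthogonality is rejected."""
    traits, meta = _parallel_dataset(17, n_per_cell=20, effect=2.0, delta=0.0)
    q = em.enumerate_quartets(meta)[0]
    p = em.bootstrap_orthogonality_test(q, traits, meta, n_boot=199, seed=8)
    assert p < 0.05
    # determinism
    assert p == em.bootstrap_orthogonality_test(q, traits, meta, n_boot=199, seed=8)


def test_classify_quartet_rules():
    assert em.classify_quartet(0.40, 0.001) == "indistinguishable_from_0"
    assert em.classify_quartet(0.001, 0.30) == "indistinguishable_from_90"
    assert em.classify_quartet(0.001, 0.001) == "between_0_and_90"
    with pytest.warns(UserWarning, match="ambiguous"):
        assert em.classify_quartet(0.40, 0.30) == "ambiguous"


def test_outlier_traits_flags_single_spike():
    t = np.zeros(132)
    t[17] = 10.0
    cols = [f"len_{i}" for i in range(132)]
    v = em.TrajectoryVector(t_values=t, contrast=("a", "b"), n_a=5, n_b=5, columns=cols)
    scan = em.outlier_traits(v)
    assert scan.flagged == {"len_17"}
    high = em.outlier_traits(v, prob=0.999999)
    assert high.flagged in (set(), {"len_17"})  # spike may survive extreme cut
    mild = em.TrajectoryVector(t_values=np.linspace(-0.1, 0.1, 132), contrast=("a", "b"), n_a=5, n_b=5)
    assert em.outlier_traits(mild, prob=0.999999).flagged == set()
    const = em.TrajectoryVector(t_values=np.ones(132), contrast=("a", "b"), n_a=5, n_b=5)
    with pytest.raises(ValueError, match="constant"):
        em.outlier_traits(const)


def test_outlier_expected_count_on_normal_vectors(rng):
    """Two-sided 95th-percentile scan flags about 13.2 of 132 iid traits."""
    counts = [
        len(em.outlier_traits(
            em.TrajectoryVector(t_values=rng.normal(size=132), contrast=("a", "b"), n_a=2, n_b=2)
        ).flagged)
        for _ in range(1000)
    ]
    assert np.mean(counts) == pytest.approx(13.2, abs=1.0)


def test_angle_method_correlation_on_radiation(paper_design_radiation):
    rad = paper_design_radiation
    tm = em.standardize(rad.traits)
    qs = em.enumerate_quartets(rad.metadata)[:12]
    r = em.angle_method_correlation(qs, tm.values, rad.metadata)
    assert r > 0.9
    with pytest.raises(ValueError, match="three"):
        em.angle_method_correlation(qs[:2], tm.values, rad.metadata)


def test_quartet_vectors_symmetry_and_L(paper_design_radiation):
    rad = paper_design_radiation
    tm = em.standardize(rad.traits)
    q = em.enumerate_quartets(rad.metadata)[0]
    v1, v2 = quartet_vectors(q, tm.values, rad.metadata)
    assert v1.L == pytest.approx(np.sqrt((v1.t_values**2).sum()), abs=1e-12)
    assert em.vector_angle(v1, v2) == pytest.approx(em.vector_angle(v2, v1))
    # L invariant under trait-column permutation
    perm = list(tm.values.columns[::-1])
    v1p, _ = quartet_vectors(q, tm.values[perm], rad.metadata)
    assert v1p.L == pytest.approx(v1.L, abs=1e-9)


def test_derive_seed_stable_and_in_range():
    s = derive_seed(123, "twig|trunk|Cuba|Jamaica")
    assert s == derive_seed(123, "twig|trunk|Cuba|Jamaica")
    assert 0 <= s < 2**31
    assert s != derive_seed(123, "twig|trunk|Cuba|Hispaniola")
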