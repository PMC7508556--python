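"""Procrustes superimposition, scaling, imputation, repeatability, PCA."""

import numpy as np
import pandas as pd
import pytest

import ecomorph as em
from ecomorph.morphometry import (
    GPAResult,
    LandmarkConfiguration,
    procrustes_distance,
)


def _config(coords, structure="pelvic", side="left"):
    return LandmarkConfiguration(structure=structure, side=side, coords=coords)


def _random_config(rng, structure="pelvic", side="left", scale=1.0):
    return _config(scale * rng.normal(size=(18, 3)), structure, side)


def _similarity_transform(coords, rng, scale=None):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    s = scale if scale is not None else rng.uniform(0.5, 2.0)
    return s * coords @ q.T + rng.normal(size=3)


def _opa_oracle(a, b):
    """Closed-form ordinary Procrustes distance between two configurations.

    Independent of the iterative GPA path: center, unit-scale, and use the
    trace of singular values of the cross-product (rotation-only optimum).
    """
    za = a - a.mean(axis=0)
    za /= np.sqrt((za**2).sum())
    zb = b - b.mean(axis=0)
    zb /= np.sqrt((zb**2).sum())
    u, s, vt = np.linalg.svd(za.T @ zb)
    det = np.linalg.det(u @ vt)
    s[-1] *= np.sign(det)
    return np.sqrt(max(2.0 - 2.0 * s.sum(), 0.0))


# mirroring ----------------------------------------------------------------


def test_mirror_negates_axis_and_is_involutive(rng):
    cfg = _random_config(rng, side="right")
    mirrored = em.mirror_configuration(cfg, axis="x")
    assert mirrored.side == "left"
    assert np.array_equal(mirrored.coords[:, 0], -cfg.coords[:, 0])
    assert np.array_equal(mirrored.coords[:, 1:], cfg.coords[:, 1:])
    back = em.mirror_configuration(mirrored, axis="x")
    assert np.array_equal(back.coords, cfg.coords)
    with pytest.raises(ValueError):
        em.mirror_configuration(cfg, axis="w")


def test_mirrored_configuration_realigns_to_original(rng):
    left = _random_config(rng, side="left")
    fake_right = LandmarkConfiguration("pelvic", "right", left.coords * np.array([-1, 1, 1]))
    recovered = em.mirror_configuration(fake_right, axis="x")
    res = em.gpa([left, recovered])
    assert procrustes_distance(res.aligned[0], res.aligned[1]) < 1e-9


# centroid size ------------------------------------------------------------


def test_centroid_size_square_and_invariances(rng):
    square = np.zeros((18, 3))
    square[:4, :2] = [(0, 0), (1, 0), (1, 1), (0, 1)]
    # only the 4 distinct corners matter: pad the rest at the centroid
    square[4:] = square[:4].mean(axis=0)
    cs = em.centroid_size(_config(square))
    assert cs == pytest.approx(np.sqrt(2.0))
    cfg = _random_config(rng)
    cs0 = em.centroid_size(cfg)
    assert em.centroid_size(_config(3.5 * cfg.coords)) == pytest.approx(3.5 * cs0)
    assert em.centroid_size(_config(cfg.coords + [5, -2, 7])) == pytest.approx(cs0)


# GPA ----------------------------------------------------------------------


def test_gpa_single_configuration(rng):
    cfg = _random_config(rng, scale=4.0)
    res = em.gpa([cfg])
    centered = cfg.coords - cfg.coords.mean(axis=0)
    expected = centered / np.sqrt((centered**2).sum())
    assert np.allclose(res.aligned[0], expected, atol=1e-12)
    assert res.centroid_sizes[0] == pytest.approx(em.centroid_size(cfg))


def test_gpa_similarity_invariance(rng):
    base = _random_config(rng)
    copy = _config(_similarity_transform(base.coords, rng))
    res = em.gpa([base, copy])
    assert procrustes_distance(res.aligned[0], res.aligned[1]) < 1e-8
    assert np.allclose(np.linalg.norm(res.aligned.mean(axis=1), axis=1), 0, atol=1e-9)
    assert np.allclose([np.sqrt((a**2).sum()) for a in res.aligned], 1, atol=1e-9)


def test_gpa_matches_two_configuration_oracle(rng):
    a = rng.normal(size=(18, 3))
    b = a + 0.1 * rng.normal(size=(18, 3))
    res = em.gpa([_config(a), _config(b)])
    observed = procrustes_distance(res.aligned[0], res.aligned[1])
    assert observed == pytest.approx(_opa_oracle(a, b), abs=1e-9)


def test_gpa_invariant_to_input_similarity_transforms(rng):
    configs = [_random_config(rng) for _ in range(5)]
    res1 = em.gpa(configs)
    transformed = [_config(_similarity_transform(c.coords, rng)) for c in configs]
    res2 = em.gpa(transformed)
    # align the two mean shapes before comparing coordinates
    from ecomorph.morphometry import _optimal_rotation

    r = _optimal_rotation(res2.mean_shape, res1.mean_shape)
    for i in range(5):
        assert np.allclose(res2.aligned[i] @ r, res1.aligned[i], atol=1e-8)


def test_gpa_recovers_template_from_noisy_copies(rng):
    template = rng.normal(size=(18, 3))
    noise = 0.01
    configs = [
        _config(_similarity_transform(template + noise * rng.normal(size=(18, 3)), rng))
        for _ in range(5)
    ]
    res = em.gpa(configs)
    zt = template - template.mean(axis=0)
    zt /= np.sqrt((zt**2).sum())
    from ecomorph.morphometry import _optimal_rotation

    aligned_t = res.mean_shape @ _optimal_rotation(res.mean_shape, zt)
    assert procrustes_distance(aligned_t, zt) < 10 * noise


def test_gpa_rejects_degenerate_and_mixed_inputs(rng):
    with pytest.raises(ValueError, match="zero centroid size"):
        em.gpa([_config(np.ones((18, 3)))])
    with pytest.raises(ValueError, match="mirror"):
        em.gpa([_random_config(rng), _random_config(rng, side="right")])
    with pytest.raises(ValueError, match="structure"):
        em.gpa([_random_config(rng, structure="pelvic"), _random_config(rng, structure="pectoral")])


# imputation ---------------------------------------------------------------


def test_impute_identity_without_missing(rng):
    df = pd.DataFrame(rng.normal(size=(10, 4)))
    out = em.impute_missing(df)
    pd.testing.assert_frame_equal(out, df)


def test_impute_rank1_recovery():
    u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    v = np.array([2.0, 1.0, 3.0])
    table = pd.DataFrame(np.outer(u, v))
    deleted = table.copy()
    deleted.iloc[2, 1] = np.nan
    out = em.impute_missing(deleted, q=1)
    assert out.iloc[2, 1] == pytest.approx(table.iloc[2, 1], abs=1e-6)
    # observed cells untouched
    mask = ~deleted.isna()
    assert np.array_equal(out.values[mask.values], table.values[mask.values])


def test_impute_all_missing_column_errors():
    df = pd.DataFrame(np.ones((5, 3)))
    df.iloc[:, 1] = np.nan
    with pytest.raises(ValueError, match="entirely missing"):
        em.impute_missing(df)


def test_impute_beats_column_mean_under_rank2(rng):
    n, p = 60, 10
    scores = rng.normal(size=(n, 2))
    loadings = rng.normal(size=(2, p))
    table = pd.DataFrame(scores @ loadings + 0.01 * rng.normal(size=(n, p)))
    masked, mask = em.inject_missing(table, 0.05, seed=4)
    out = em.impute_missing(masked, q=2)
    truth = table.values[mask.values]
    rmse_pca = np.sqrt(np.mean((out.values[mask.values] - truth) ** 2))
    col_means = np.nanmean(masked.values, axis=0)
    naive = np.take(col_means, np.where(mask.values)[1])
    rmse_naive = np.sqrt(np.mean((naive - truth) ** 2))
    assert rmse_pca < rmse_naive


# size correction & standardization ---------------------------------------


def test_size_correct_division_and_scale_invariance():
    linear = pd.DataFrame({"len_femur": [10.0, 20.0]}, index=["a", "b"])
    sizes = pd.Series([5.0, 5.0], index=["a", "b"])
    out = em.size_correct(linear, sizes)
    assert out.loc["a", "len_femur"] == pytest.approx(2.0)
    doubled = em.size_correct(linear * 2, sizes * 2)
    pd.testing.assert_frame_equal(doubled, out)
    with pytest.raises(ValueError, match="positive"):
        em.size_correct(linear, pd.Series([5.0, 0.0], index=["a", "b"]))


def test_standardize_hand_example_and_idempotence():
    raw = pd.DataFrame({"len_femur": [1.0, 2.0, 3.0], "thick_femur_diam": [2.0, 4.0, 9.0]})
    tm = em.standardize(raw)
    assert np.allclose(tm.values["len_femur"], [-1, 0, 1])
    assert tm.scaling_record.loc["len_femur", "sd"] == pytest.approx(1.0)
    again = em.standardize(tm.values)
    assert np.allclose(again.values.to_numpy(), tm.values.to_numpy(), atol=1e-12)
    with pytest.raises(ValueError, match="len_femur"):
        em.standardize(pd.DataFrame({"len_femur": [1.0, 1.0, 1.0]}))


def test_standardize_projection_of_new_rows():
    raw = pd.DataFrame({"len_femur": [1.0, 2.0, 3.0, 4.0]})
    tm = em.standardize(raw)
    new = pd.DataFrame({"len_femur": [2.5]})
    assert tm.project(new).iloc[0, 0] == pytest.approx(0.0)


# assembly ----------------------------------------------------------------


def test_assemble_traits_shapes_and_classes(small_study):
    raw = em.prepare_study(small_study)
    assert raw.shape[1] == 132
    from ecomorph.morphometry import classify_columns

    classes = classify_columns(raw.columns)
    assert (classes == "shape").sum() == 108
    assert (classes == "length").sum() == 15
    assert (classes == "thickness").sum() == 8
    assert (classes == "size").sum() == 1
    tm = em.standardize(raw)
    assert np.abs(tm.values.mean(axis=0)).max() < 1e-10
    assert np.abs(tm.values.std(axis=0, ddof=1) - 1).max() < 1e-10


def test_assemble_excludes_specimen_missing_one_girdle(small_study):
    study = small_study
    broken_id = list(study.landmarks)[0]
    landmarks = {sid: dict(v) for sid, v in study.landmarks.items()}
    del landmarks[broken_id]["pelvic"]
    import dataclasses

    study2 = dataclasses.replace(study, landmarks=landmarks)
    with pytest.warns(UserWarning, match="lacking one girdle"):
        raw = em.prepare_study(study2)
    assert broken_id not in raw.index


# repeatability ------------------------------------------------------------


def test_repeatability_identical_replicates_gives_one(rng):
    reps = {}
    for ind in range(3):
        cfg = _random_config(rng)
        reps[f"ind{ind}"] = [cfg, _config(cfg.coords.copy())]
    res = em.repeatability(reps)
    assert res.R == pytest.approx(1.0)
    assert res.ms_within == pytest.approx(0.0, abs=1e-20)


def test_repeatability_no_individual_signal_near_zero(rng):
    template = rng.normal(size=(18, 3))
    reps = {
        f"ind{i}": [_config(template + 0.05 * rng.normal(size=(18, 3))) for _ in range(2)]
        for i in range(50)
    }
    res = em.repeatability(reps)
    assert res.R < 0.25


def test_repeatability_matches_hand_anova(rng):
    """Two individuals, two replicates: R from the aligned coordinates must
    equal a brute-force one-way ANOVA on those same coordinates."""
    base = rng.normal(size=(18, 3))
    shift = rng.normal(size=(18, 3))
    reps = {
        "a": [_config(base), _config(base + 0.01 * shift)],
        "b": [_config(base + 0.3 * shift), _config(base + 0.31 * shift)],
    }
    res = em.repeatability(reps)
    # brute-force oracle on the aligned coordinates
    aligned = em.gpa([c for ind in ("a", "b") for c in reps[ind]]).aligned.reshape(4, -1)
    groups = [aligned[:2], aligned[2:]]
    grand = aligned.mean(axis=0)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum() for g in groups)
    ss_among = sum(2 * ((g.mean(axis=0) - grand) ** 2).sum() for g in groups)
    ms_a, ms_w = ss_among / 1, ss_within / 2
    s2a = (ms_a - ms_w) / 2
    assert res.R == pytest.approx(s2a / (s2a + ms_w), abs=1e-12)


def test_repeatability_scale_invariance(rng):
    reps = {
        f"ind{i}": [_random_config(rng), _random_config(rng)] for i in range(4)
    }
    r1 = em.repeatability(reps).R
    scaled = {
        k: [_config(7.7 * c.coords, c.structure, c.side) for c in v] for k, v in reps.items()
    }
    assert em.repeatability(scaled).R == pytest.approx(r1, abs=1e-10)


# PCA ----------------------------------------------------------------------


def test_pca_isotropic_gaussian_fractions(rng):
    x = pd.DataFrame(rng.normal(size=(1000, 3)), columns=["len_a", "len_b", "len_c"])
    res = em.pca_variance(x)
    assert np.allclose(res.variance_fractions, 1 / 3, atol=0.05)
    assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_line_data_and_orthonormal_loadings(rng):
    t = rng.normal(size=200)
    x = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
    res = em.pca_variance(x)
    assert res.variance_fractions[0] == pytest.approx(1.0)
    gram = res.loadings.T @ res.loadings
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
    assert np.all(np.diff(res.variance_fractions) <= 1e-12)


def test_pca_species_mean_level(paper_design_radiation):
    rad = paper_design_radiation
    tm = em.standardize(rad.traits)
    res = em.pca_variance(tm, level="species-mean", species=rad.metadata["species"])
    assert res.scores.shape[0] == rad.metadata["species"].nunique()
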