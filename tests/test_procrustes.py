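"""Procrustes machinery: alignment, sliding, symmetry, TPS warps."""

import numpy as np
import pytest

from morphodim import (
    BendingEnergyModel,
    centroid_size,
    gpa,
    opa_align,
    slide_semilandmarks,
    symmetrize,
    tps_warp,
)
from morphodim.procrustes import _relabel_pairs, _unit


def rot2(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


# --- centroid size ---------------------------------------------------------


def test_centroid_size_unit_square():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    assert centroid_size(square) == pytest.approx(np.sqrt(2.0))


def test_centroid_size_homogeneous(rng):
    x = rng.normal(size=(9, 2))
    assert centroid_size(3.7 * x) == pytest.approx(3.7 * centroid_size(x))


def test_centroid_size_degenerate():
    with pytest.raises(ValueError):
        centroid_size(np.ones((5, 2)))


# --- ordinary Procrustes ---------------------------------------------------


def test_opa_recovers_rotation(rng):
    ref = rng.normal(size=(8, 2))
    ref -= ref.mean(axis=0)
    target = ref @ rot2(np.deg2rad(30)).T
    aligned, rec = opa_align(target, ref)
    assert rec.residual < 1e-9
    np.testing.assert_allclose(aligned, ref, atol=1e-9)


def test_opa_mirror_without_reflection_has_positive_residual(rng):
    ref = rng.normal(size=(6, 2))
    ref -= ref.mean(axis=0)
    mirrored = ref * [-1.0, 1.0]
    _, rec = opa_align(mirrored, ref, allow_reflection=False)
    assert rec.reflected
    assert rec.residual > 1e-3
    _, rec_ok = opa_align(mirrored, ref, allow_reflection=True)
    assert rec_ok.residual < 1e-9


def test_opa_matches_brute_force_rotation_grid(rng):
    """Optimal angle agrees with a fine exhaustive search over rotations."""
    x = rng.normal(size=(5, 2))
    y = rng.normal(size=(5, 2))
    x -= x.mean(axis=0)
    y -= y.mean(axis=0)
    aligned, rec = opa_align(x, y, scale=False)
    angles = np.deg2rad(np.arange(0.0, 360.0, 0.001))
    # residual^2 = |x|^2 + |y|^2 - 2 (cos a * A + sin a * B)
    a_term = np.trace(x.T @ y)
    b_term = x[:, 1] @ y[:, 0] - x[:, 0] @ y[:, 1]
    scores = np.cos(angles) * a_term + np.sin(angles) * b_term
    best = angles[np.argmax(scores)]
    opt = np.arctan2(rec.rotation[1, 0], rec.rotation[0, 0]) % (2 * np.pi)
    assert abs((opt - best + np.pi) % (2 * np.pi) - np.pi) < np.deg2rad(0.001)


# --- GPA -------------------------------------------------------------------


def test_gpa_collapses_similarity_copies(template, scheme, rng):
    base = template.coords
    copies = []
    for _ in range(6):
        x = base @ rot2(rng.uniform(0, 2 * np.pi)).T
        copies.append(x * rng.uniform(0.3, 3.0) + rng.normal(0, 50, 2))
    res = gpa(copies, scheme, slide=False)
    assert np.abs(res.aligned - res.aligned[0]).max() < 1e-8
    assert np.abs(res.consensus - res.aligned[0]).max() < 1e-8
    # consensus centered, shapes at unit centroid size
    assert np.abs(res.consensus.mean(axis=0)).max() < 1e-9
    for shape in res.aligned:
        assert centroid_size(shape) == pytest.approx(1.0, abs=1e-9)


def test_gpa_invariance_under_input_transforms(template, scheme, rng):
    base = template.coords
    shapes = [base + rng.normal(0, 0.4, base.shape) for _ in range(8)]
    res1 = gpa(shapes, scheme, slide=False)
    moved = [s.copy() for s in shapes]
    moved[3] = moved[3] @ rot2(1.1).T * 2.5 + [40.0, -7.0]
    res2 = gpa(moved, scheme, slide=False)
    d = res2.aligned[3] - res1.aligned[3]
    assert np.abs(d).max() < 1e-6
    assert res2.centroid_sizes[3] == pytest.approx(2.5 * res1.centroid_sizes[3])


def test_gpa_two_shapes_consensus_equidistant(template, scheme, rng):
    a = template.coords + rng.normal(0, 0.8, template.coords.shape)
    b = template.coords + rng.normal(0, 0.8, template.coords.shape)
    res = gpa([a, b], scheme, slide=False)
    d0 = np.sqrt(np.sum((res.aligned[0] - res.consensus) ** 2))
    d1 = np.sqrt(np.sum((res.aligned[1] - res.consensus) ** 2))
    assert d0 == pytest.approx(d1, abs=1e-9)


def test_gpa_matches_alternating_minimization_restarts(template, scheme, rng):
    """Consensus agrees with an explicit alternating-minimization reference
    run from several random starting consensuses."""
    base = _unit(template.coords)
    shapes = [base + rng.normal(0, 0.02, base.shape) for _ in range(20)]
    res = gpa(shapes, scheme, slide=False)

    def reference_fit(start):
        cons = _unit(start)
        work = [_unit(s) for s in shapes]
        for _ in range(300):
            work = [_unit(opa_align(s, cons, scale=True)[0]) for s in work]
            new = _unit(np.mean(work, axis=0))
            if np.sqrt(np.sum((new - cons) ** 2)) < 1e-12:
                cons = new
                break
            cons = new
        score = sum(np.sum((w - cons) ** 2) for w in work)
        return cons, score

    best = None
    for i in rng.choice(len(shapes), size=5, replace=False):
        start = shapes[i] @ rot2(rng.uniform(0, 2 * np.pi)).T
        cons, score = reference_fit(start)
        if best is None or score < best[1]:
            best = (cons, score)
    aligned_ref, _ = opa_align(best[0], res.consensus, scale=True)
    assert np.abs(_unit(aligned_ref) - res.consensus).max() < 1e-6


# --- bending energy and sliding -------------------------------------------


def test_bending_energy_zero_for_affine(template):
    model = BendingEnergyModel(template.coords)
    affine = template.coords @ np.array([[1.3, 0.2], [-0.1, 0.9]]).T + [5.0, -2.0]
    assert model.energy(affine) < 1e-9
    b = model.energy_matrix
    np.testing.assert_allclose(b, b.T, atol=1e-12)
    eigs = np.linalg.eigvalsh(b)
    assert eigs.min() > -1e-9


def test_slide_noop_at_consensus(template, scheme):
    cons = _unit(template.coords)
    out = slide_semilandmarks([cons.copy()], cons, scheme)
    np.testing.assert_allclose(out[0], cons, atol=1e-9)


def test_slide_recovers_tangent_displacement(template, scheme):
    cons = _unit(template.coords)
    j = scheme.semilandmarks[0]
    a, _, c = scheme.sliders[j]
    tangent = cons[c] - cons[a]
    tangent /= np.linalg.norm(tangent)
    moved = cons.copy()
    moved[j] += 0.01 * tangent
    model = BendingEnergyModel(cons)
    e_before = model.energy(moved)
    out = slide_semilandmarks([moved], cons, scheme, model)
    e_after = model.energy(out[0])
    assert e_after < e_before
    assert np.abs(out[0][j] - cons[j]).max() < 1e-6


def test_slide_never_increases_energy(template, scheme, rng):
    cons = _unit(template.coords)
    model = BendingEnergyModel(cons)
    configs = [cons + rng.normal(0, 0.004, cons.shape) for _ in range(10)]
    out = slide_semilandmarks(configs, cons, scheme, model)
    for before, after in zip(configs, out):
        assert model.energy(after) <= model.energy(before) + 1e-12


def test_slide_matches_grid_search_on_toy_arc():
    """Three sliding points on an arc: solver energy matches an exhaustive
    (iteratively refined) grid search over the sliding amounts."""
    from morphodim.landmarks import LandmarkScheme

    theta = np.deg2rad(np.array([0.0, 30.0, 60.0, 90.0, 120.0]))
    cons = np.column_stack([np.cos(theta), np.sin(theta)])
    extra = np.array([[0.0, 0.0], [0.5, -0.5]])
    cons = np.vstack([cons, extra])
    cons -= cons.mean(axis=0)
    scheme = LandmarkScheme(
        names=tuple(f"p{i}" for i in range(7)),
        roles=("fixed", "semilandmark", "semilandmark", "semilandmark", "fixed", "fixed", "fixed"),
        bilateral_pairs=(),
        midline=tuple(range(7)),
        sliders={1: (0, 1, 2), 2: (1, 2, 3), 3: (2, 3, 4)},
    )
    rng = np.random.default_rng(3)
    config = cons + rng.normal(0, 0.02, cons.shape)
    model = BendingEnergyModel(cons)
    out = slide_semilandmarks([config], cons, scheme, model)
    e_solver = model.energy(out[0])

    # grid-search oracle over the three sliding amounts, coarse-to-fine
    tangents = {}
    for j, (a, _, c) in scheme.sliders.items():
        t = config[c] - config[a]
        tangents[j] = t / np.linalg.norm(t)

    def energy_of(alphas):
        x = config.copy()
        for (j, t), al in zip(tangents.items(), alphas):
            x[j] = config[j] + al * t
        return model.energy(x)

    center = np.zeros(3)
    width = 0.1
    for _ in range(4):
        grids = [np.linspace(c - width, c + width, 21) for c in center]
        best = None
        for a0 in grids[0]:
            for a1 in grids[1]:
                for a2 in grids[2]:
                    e = energy_of([a0, a1, a2])
                    if best is None or e < best[0]:
                        best = (e, np.array([a0, a1, a2]))
        center, width = best[1], width / 10.0
    assert e_solver == pytest.approx(best[0], abs=1e-6)


# --- symmetrization --------------------------------------------------------


def test_symmetrize_fixed_point(template, scheme):
    out = symmetrize(template, scheme)
    centered = template.coords - template.coords.mean(axis=0)
    assert np.abs(out.coords - centered).max() < 1e-9


def test_symmetrize_idempotent_and_exactly_mirror(template, scheme, rng):
    noisy = template.coords + rng.normal(0, 0.5, template.coords.shape)
    once = symmetrize(noisy, scheme)
    twice = symmetrize(once, scheme)
    assert np.abs(np.asarray(twice) - np.asarray(once)).max() < 1e-9
    out = np.asarray(once)
    mirrored = _relabel_pairs(out * [-1.0, 1.0], scheme)
    assert np.abs(mirrored - out).max() < 1e-9
    assert np.abs(out[list(scheme.midline), 0]).max() < 1e-9


def test_symmetrize_matches_hand_computed_average(toy_scheme):
    """Output equals the average of the original and its reflected,
    relabeled, OPA-fitted copy, computed independently here."""
    coords = np.array(
        [[0.05, 1.0], [0.0, -1.0], [-0.52, 0.45], [0.47, 0.52], [-0.33, -0.61], [0.30, -0.55]]
    )
    out = np.asarray(symmetrize(coords, toy_scheme))

    xc = coords - coords.mean(axis=0)
    perm = [0, 1, 3, 2, 5, 4]
    mirrored = (xc * [-1.0, 1.0])[perm]
    fitted, _ = opa_align(mirrored, xc, allow_reflection=True, scale=True)
    avg = (xc + fitted) / 2.0
    # hand-rotate so the midline (points 0, 1) is vertical, midline x = 0
    avg -= avg.mean(axis=0)
    dx, dy = avg[0] - avg[1]
    length = np.hypot(dx, dy)
    c, s = dy / length, dx / length
    expected = avg @ np.array([[c, -s], [s, c]]).T
    expected[:, 0] -= expected[[0, 1], 0].mean()
    # final exact mirror-average in the axis-aligned frame
    expected = (expected + (expected * [-1.0, 1.0])[perm]) / 2.0
    expected[[0, 1], 0] = 0.0
    assert np.abs(out - expected).max() < 1e-9
    mirrored_out = (out * [-1.0, 1.0])[perm]
    assert np.abs(mirrored_out - out).max() < 1e-9


def test_symmetrize_requires_pairs():
    from morphodim.landmarks import LandmarkScheme

    no_pairs = LandmarkScheme(
        names=("a", "b", "c"),
        roles=("fixed",) * 3,
        bilateral_pairs=(),
        midline=(0, 1, 2),
    )
    with pytest.raises(ValueError):
        symmetrize(np.eye(3, 2), no_pairs)


# --- TPS warp --------------------------------------------------------------


def test_tps_identity_and_affine(rng):
    src = rng.normal(size=(7, 2))
    q = rng.normal(size=(30, 2))
    np.testing.assert_allclose(tps_warp(src, src, q), q, atol=1e-9)
    amat = np.array([[1.4, 0.3], [-0.2, 0.8]])
    tgt = src @ amat.T + [2.0, -1.0]
    np.testing.assert_allclose(tps_warp(src, tgt, q), q @ amat.T + [2.0, -1.0], atol=1e-8)
    model = BendingEnergyModel(src)
    assert model.energy(tgt) < 1e-9


def test_tps_matches_independent_assembly(rng):
    """Warped grid nodes agree with an independently assembled TPS system."""
    src = rng.normal(size=(6, 2))
    tgt = src + rng.normal(0, 0.3, src.shape)
    gx, gy = np.meshgrid(np.linspace(-2, 2, 7), np.linspace(-2, 2, 7))
    q = np.column_stack([gx.ravel(), gy.ravel()])
    got = tps_warp(src, tgt, q)

    def u(r2):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(r2 > 0, r2 * np.log(r2), 0.0)

    k = src.shape[0]
    expected = np.zeros_like(got)
    for axis in range(2):
        lhs = np.zeros((k + 3, k + 3))
        for i in range(k):
            for j in range(k):
                lhs[i, j] = u(np.sum((src[i] - src[j]) ** 2))
            lhs[i, k] = 1.0
            lhs[i, k + 1 :] = src[i]
            lhs[k, i] = 1.0
            lhs[k + 1 :, i] = src[i]
        rhs = np.concatenate([tgt[:, axis], np.zeros(3)])
        sol = np.linalg.solve(lhs, rhs)
        for m, point in enumerate(q):
            val = sol[k] + sol[k + 1] * point[0] + sol[k + 2] * point[1]
            for i in range(k):
                val += sol[i] * u(np.sum((point - src[i]) ** 2))
            expected[m, axis] = val
    assert np.abs(got - expected).max() < 1e-8


def test_tps_duplicate_source_rejected():
    src = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(ValueError):
        tps_warp(src, src, np.zeros((1, 2)))
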