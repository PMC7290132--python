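import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from biofilmnet import diversity, module_env as me, preprocess
from biofilmnet.exceptions import ValidationError
from biofilmnet.simulate import SimulationConfig, generate_community


def _dm_from_points(rng, n, d=2):
    pts = rng.normal(size=(n, d))
    dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(dist, [f"s{i}" for i in range(n)])


def test_module_distance_full_module_equals_whole_community(rel_table):
    partition = {otu: 0 for otu in rel_table.columns}
    d_mod = me.module_subcommunity_distance(rel_table, partition, 0)
    d_all = diversity.bray_curtis(rel_table)
    assert np.allclose(d_mod.data, d_all.data, atol=1e-12)


def test_module_distance_disjoint_support_is_one():
    rel = pd.DataFrame(
        {"m1": [0.5, 0.0], "m2": [0.2, 0.0], "other": [0.3, 1.0]},
        index=["A", "B"],
    )
    partition = {"m1": 0, "m2": 0, "other": 1}
    d = me.module_subcommunity_distance(rel, partition, 0)
    assert d["A", "B"] == 1.0


def test_module_distance_matches_bruteforce(rel_table, rng):
    otus = list(rel_table.columns[:40])
    partition = {o: 7 for o in otus}
    d = me.module_subcommunity_distance(rel_table, partition, 7)
    X = rel_table[otus].to_numpy()
    i, j = 3, 15
    expected = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
    assert d[str(rel_table.index[i]), str(rel_table.index[j])] == pytest.approx(
        expected, abs=1e-12
    )


def test_module_distance_missing_module():
    rel = pd.DataFrame(np.ones((3, 2)) / 2, columns=["a", "b"])
    with pytest.raises(ValidationError):
        me.module_subcommunity_distance(rel, {"a": 0, "b": 0}, 99)


def test_env_distance_values_and_constant():
    meta = pd.DataFrame({"x": [0.0, 1.0, 3.0], "c": [2.0, 2.0, 2.0]},
                        index=["a", "b", "c"])
    d = me.env_distance(meta, "x")
    assert d["b", "c"] == 2.0
    assert np.allclose(me.env_distance(meta, "c").data, 0)


def test_mantel_identity_and_determinism(rng):
    dA = _dm_from_points(rng, 15)
    res = me.mantel(dA, dA, n_permutations=199, seed=4)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 200)
    again = me.mantel(dA, dA, n_permutations=199, seed=4)
    assert again.p == res.p


def test_mantel_matches_skbio(rng):
    """Independent oracle: vegan-convention one-sided Mantel r from scikit-bio."""
    dA, dB = _dm_from_points(rng, 18), _dm_from_points(rng, 18)
    ours = me.mantel(dA, dB, n_permutations=999, seed=0)
    r_ref, p_ref, _ = skbio_mantel(dA, dB, permutations=999, alternative="greater",
                                   seed=1)
    assert ours.r == pytest.approx(r_ref, abs=1e-12)
    assert abs(ours.p - p_ref) < 0.05  # both permutation estimates of the same p


def test_mantel_invariant_under_joint_relabeling(rng):
    dA, dB = _dm_from_points(rng, 12), _dm_from_points(rng, 12)
    perm = rng.permutation(12)
    ids = [dA.ids[i] for i in perm]
    dA2 = DistanceMatrix(dA.data[np.ix_(perm, perm)], ids)
    dB2 = DistanceMatrix(dB.data[np.ix_(perm, perm)], ids)
    assert me.mantel(dA2, dB2, 99, seed=0).r == pytest.approx(
        me.mantel(dA, dB, 99, seed=0).r, abs=1e-12
    )


def test_mantel_size_mismatch():
    rng = np.random.default_rng(0)
    with pytest.raises(ValidationError):
        me.mantel(_dm_from_points(rng, 5), _dm_from_points(rng, 6))


def test_partial_mantel_constant_control_rejected(rng):
    dA = _dm_from_points(rng, 10)
    dC = DistanceMatrix(np.zeros((10, 10)), dA.ids)
    with pytest.raises(ValidationError, match="constant control"):
        me.partial_mantel(dA, dA, dC)


def test_partial_mantel_identical_matrices_r_near_one(rng):
    dA = _dm_from_points(rng, 15)
    dC = _dm_from_points(rng, 15)
    dC = DistanceMatrix(dC.data, dA.ids)
    res = me.partial_mantel(dA, dA, dC, n_permutations=99, seed=2)
    assert res.r > 0.95


def test_partial_mantel_uninformative_control_reduces_to_mantel(rng):
    """A control orthogonal to both matrices leaves the partial
    statistic equal to the plain Mantel r."""
    n = 15
    dA, dB = _dm_from_points(rng, n), _dm_from_points(rng, n)
    dB = DistanceMatrix(dB.data, dA.ids)
    iu = np.triu_indices(n, 1)
    x, y = dA.data[iu], dB.data[iu]
    w = rng.normal(size=len(x))
    basis = np.column_stack([np.ones_like(x), x, y])
    w -= basis @ np.linalg.lstsq(basis, w, rcond=None)[0]  # r_AC = r_BC = 0
    c = np.zeros((n, n))
    c[iu] = 1.0 + 0.01 * w / np.abs(w).max()
    dC = DistanceMatrix(c + c.T, dA.ids)
    plain = me.mantel(dA, dB, 199, seed=3)
    part = me.partial_mantel(dA, dB, dC, 199, seed=3)
    assert part.r == pytest.approx(plain.r, abs=1e-9)


def test_partial_mantel_type_i_error(rng):
    """dB independent of dA given dC: rejection stays near alpha."""
    rej = 0
    reps = 100
    for k in range(reps):
        z = rng.normal(size=(14, 2))
        dA = _dm_from_points(rng, 14)
        y = rng.normal(size=(14, 2))
        dB = DistanceMatrix(np.sqrt(((y[:, None] - y[None]) ** 2).sum(-1)), dA.ids)
        dC = DistanceMatrix(np.sqrt(((z[:, None] - z[None]) ** 2).sum(-1)), dA.ids)
        res = me.partial_mantel(dA, dB, dC, 199, seed=k)
        rej += res.p <= 0.05
    assert 0.0 <= rej / reps <= 0.12


def test_screen_gradient_module_detected_and_control_na():
    """A planted module tracking the NDVI gradient shows a significant
    Mantel r; the control variable's partial column is not applicable."""
    cfg = SimulationConfig(
        n_samples=50, n_otus=200, depth_mean=4000, depth_sd=400,
        n_planted_modules=2, module_size=20, frac_env_responsive=0.4, seed=31,
    )
    table, meta, _, truth = generate_community(cfg)
    rel = preprocess.relative_abundance(table)
    # module 0 = responsive OTUs (tracks the gradient); module 1 = a planted module
    resp = [o for o in truth.responsive_otus if o not in truth.module_membership]
    partition = {o: 0 for o in resp}
    partition.update({o: 1 for o, m in truth.module_membership.items() if m == 0})
    screen = me.module_env_screen(
        rel, partition, meta, ["NDVI", "Altitude"], control="Altitude",
        min_module_size=10, n_permutations=199, seed=8,
    )
    ndvi_row = screen[(screen["module"] == 0) & (screen["variable"] == "NDVI")]
    assert ndvi_row["mantel_p"].iloc[0] <= 0.05
    alt_rows = screen[screen["variable"] == "Altitude"]
    assert alt_rows["partial_r"].isna().all()


def test_screen_shuffled_environment_null(rng):
    cfg = SimulationConfig(
        n_samples=30, n_otus=150, depth_mean=3000, depth_sd=300,
        n_planted_modules=2, module_size=20, frac_env_responsive=0.0, seed=41,
    )
    table, meta, _, truth = generate_community(cfg)
    rel = preprocess.relative_abundance(table)
    meta = meta.copy()
    for col in meta.columns:  # break any community-environment link
        meta[col] = rng.permutation(meta[col].to_numpy())
    partition = dict(truth.module_membership)
    screen = me.module_env_screen(
        rel, partition, meta, ["NDVI", "pH", "Cond"], min_module_size=10,
        n_permutations=199, seed=2,
    )
    assert (screen["mantel_p_adjusted"] <= 0.05).mean() <= 0.2
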