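import numpy as np
import pytest

from eics.interpolation import (
    SampledKSpace,
    eics_interpolate,
    fics_interpolate,
    interpolate_stack,
    load_undersampled,
    provenance_table,
    save_undersampled,
    set_difference,
    set_union,
    undersample_stack,
)
from eics.phantom import PhantomSpec, generate_phantom
from eics.trajectories import make_mask_triple


@pytest.fixture(scope="module")
def under():
    stack = generate_phantom(PhantomSpec(n_slices=6, matrix_size=64, noise_sigma=0.0, seed=7))
    triple = make_mask_triple(4, "golden", 64)
    return undersample_stack(stack, triple, gap=0)


def _kset(coords, values=None, **kw):
    coords = np.asarray(coords, float)
    if values is None:
        values = np.arange(1, len(coords) + 1, dtype=complex)
    return SampledKSpace.from_samples(coords, values, **kw)


def test_undersample_mask_cycling_and_counts(under):
    n_spokes, n_read = 4, 64
    assert [s.source_mask for s in under.slices] == ["R1", "R2", "R3", "R1", "R2", "R3"]
    np.testing.assert_array_equal(under.triple_assignment, [0, 1, 2, 0, 1, 2])
    # unique locations: full-diameter spokes share exactly one DC sample
    for s in under.slices:
        assert len(s) == n_spokes * (n_read - 1) + 1


def test_undersample_gap_decimation():
    stack = generate_phantom(PhantomSpec(n_slices=12, matrix_size=64, seed=0))
    triple = make_mask_triple(3, "uniform", 64)
    assert undersample_stack(stack, triple, gap=1).n_slices == 6
    assert undersample_stack(stack, triple, gap=2).n_slices == 4
    with pytest.raises(ValueError):
        undersample_stack(stack, triple, gap=5)


def test_undersample_zero_stack_gives_zero_values():
    from eics.phantom import SliceStack

    stack = SliceStack(data=np.zeros((3, 64, 64)))
    triple = make_mask_triple(2, "uniform", 64)
    u = undersample_stack(stack, triple)
    for s in u.slices:
        assert np.allclose(s.values, 0.0)
        assert len(s) == 2 * 63 + 1


def test_set_difference_identities():
    a = _kset([[0.1, 0.0], [0.2, 0.0], [0.3, 0.0]])
    empty = set_difference(a, a)
    assert len(empty) == 0
    b = _kset([[0.4, 0.1]])
    got = set_difference(a, set_difference(b, b))
    assert len(got) == len(a)
    np.testing.assert_array_equal(got.keys, a.keys)


def test_set_difference_between_spokes_removes_shared_dc(under):
    l, t = under.slices[0], under.slices[1]
    # masks are disjoint except for the DC point every spoke contains
    assert len(set_difference(l, t)) == len(l) - 1


def test_set_union_disjoint_additivity():
    a = _kset([[0.1, 0.0]])
    b = _kset([[0.2, 0.0], [0.3, 0.0]])
    u = set_union([a, b])
    assert len(u) == 3
    assert len(set_union([a, set_difference(b, b)])) == 1


def test_set_union_collision_keeps_earlier_entry(caplog):
    a = _kset([[0.1, 0.0]], values=[1.0 + 0j])
    b = _kset([[0.1, 0.0]], values=[2.0 + 0j])
    with caplog.at_level("WARNING"):
        u = set_union([a, b])
    assert len(u) == 1
    assert u.values[0] == 1.0 + 0j
    assert any("colliding" in r.message for r in caplog.records)


def test_eics_count_conservation_and_target_preservation(under):
    l, t, r = under.slices[0], under.slices[1], under.slices[2]
    out = eics_interpolate(l, t, r)
    assert len(out) == len(t) + len(set_difference(l, t)) + len(set_difference(r, t))
    # every target sample survives with its value intact
    pos = {k: v for k, v in zip(out.keys, out.values)}
    for k, v in zip(t.keys, t.values):
        assert pos[k] == v
    # provenance partition
    frac_t = np.mean(out.provenance == "T")
    frac_l = np.mean(out.provenance == "L")
    frac_r = np.mean(out.provenance == "R")
    assert frac_t + frac_l + frac_r == pytest.approx(1.0)
    assert frac_t >= frac_l and frac_t >= frac_r


def test_eics_idempotent_on_identical_slices(under):
    t = under.slices[0]
    out = eics_interpolate(t, t, t)
    assert len(out) == len(t)
    np.testing.assert_array_equal(np.sort(out.keys), np.sort(t.keys))


def test_fics_subset_of_eics(under):
    l, t, r = under.slices[0], under.slices[1], under.slices[2]
    f = fics_interpolate(l, t)
    e = eics_interpolate(l, t, r)
    assert len(f) == len(t) + len(l) - 1  # one shared DC location
    assert np.isin(f.keys, e.keys).all()


def test_interpolate_stack_counts_and_passthrough(under):
    none = interpolate_stack(under, "none")
    for a, b in zip(none.slices, under.slices):
        np.testing.assert_array_equal(a.keys, b.keys)
        np.testing.assert_array_equal(a.values, b.values)
    e = interpolate_stack(under, "eics")
    n_per = len(under.slices[0])
    interior = [len(s) for s in e.slices[1:-1]]
    assert len(set(interior)) == 1  # period-3 cycling: identical counts
    assert interior[0] == 3 * (n_per - 1) + 1
    # boundary slices degrade to the one-neighbor rule
    assert len(e.slices[0]) == 2 * (n_per - 1) + 1
    assert len(e.slices[-1]) == 2 * (n_per - 1) + 1
    with pytest.raises(ValueError):
        interpolate_stack(under, "vrdu")


def test_provenance_table_contents(under):
    e = interpolate_stack(under, "eics")
    tab = provenance_table(e)
    per_slice = tab.drop(index="mean")
    np.testing.assert_allclose(
        per_slice[["pct_T", "pct_L", "pct_R"]].sum(axis=1), 100.0
    )
    interior = per_slice.iloc[1:-1]
    assert ((interior["pct_T"] >= 33.0) & (interior["pct_T"] <= 35.0)).all()
    none = interpolate_stack(under, "none")
    tab0 = provenance_table(none)
    assert (tab0.drop(index="mean")["pct_T"] == 100.0).all()
    assert (tab0.drop(index="mean")["pct_L"] == 0.0).all()


def test_provenance_requires_tags(under):
    with pytest.raises(ValueError):
        provenance_table(under)


def test_undersampled_stack_roundtrip(tmp_path, under):
    e = interpolate_stack(under, "eics")
    path = tmp_path / "stack.npz"
    save_undersampled(e, path)
    back = load_undersampled(path)
    assert back.n_slices == e.n_slices
    assert back.method == "eics"
    for a, b in zip(back.slices, e.slices):
        np.testing.assert_array_equal(a.keys, b.keys)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.provenance, b.provenance)
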