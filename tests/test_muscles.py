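"""Activation schedules, phoneme preset tables, sigma_max defaults, and the
Genioglossus 4-unit partition."""
import numpy as np
import pytest

from tonguefem import (ActivationSchedule, PhantomSpec, evaluate_schedule,
                       generate_tongue_phantom, schedule_from_table)
from tonguefem.muscles import (build_genioglossus_partition,
                               check_preset_consistency, default_sigma_max,
                               jaw_hyoid_displacements, load_presets)


# ----------------------------------------------------------- preset table
def test_preset_table_values():
    t = load_presets()["active_stresses_pa"]
    assert t["i"] == {"GGa": 3500, "GGm": 0, "GGp": 4000, "GGh": 10000,
                      "SG": 0, "HG": 0, "Vert": 0, "Trans": 0, "IL": 0,
                      "SL": 0, "GH": 6000, "MH": 0}
    assert t["u"]["SG"] == 90000 and t["u"]["GGh"] == 35000


def test_schedule_from_table_a_and_k():
    a = {s.muscle: s.plateau for s in schedule_from_table("a")}
    assert a == {"GGa": 8000, "GGm": 8000, "GGh": 2000, "SG": 20000,
                 "HG": 3000, "IL": 5000}
    k = {s.muscle: s.plateau for s in schedule_from_table("k")}
    assert k == {"GGh": 6000, "SG": 70000, "GH": 2500, "MH": 10000}
    with pytest.raises(KeyError):
        schedule_from_table("e")


def test_zero_ramp_warns():
    with pytest.warns(UserWarning, match="discontinuous"):
        scheds = schedule_from_table("i", ramp_s=0.0)
    assert all(s.breakpoints[0][1] == s.plateau for s in scheds)


def test_jaw_hyoid_table():
    t = jaw_hyoid_displacements("t")
    assert t == {"jaw_opening": 1.0, "hyoid_x": 1.1, "hyoid_y": 3.3}
    i = jaw_hyoid_displacements("i")
    assert (i["hyoid_x"], i["hyoid_y"]) == (5.8, -5.6)


def test_preset_consistency_with_reported_activations():
    """For the cardinal vowels, the nonzero preset muscles match the
    published per-model activation comparison (GGp/GGh merged)."""
    for ph in ("a", "u", "i"):
        assert check_preset_consistency(ph)


def test_default_sigma_max():
    assert default_sigma_max("SG") == pytest.approx(1.2 * 90000)
    assert default_sigma_max("GGa") == pytest.approx(1.2 * 15000)
    assert default_sigma_max("Trans") > 0  # never activated: floor value


# -------------------------------------------------------------- schedules
def test_schedule_evaluation():
    s = ActivationSchedule("GGa", [(0.0, 0.0), (0.2, 10000.0), (1.0, 10000.0)])
    assert evaluate_schedule(s, 0.1) == pytest.approx(5000.0)
    assert evaluate_schedule(s, 0.2) == 10000.0
    assert evaluate_schedule(s, 5.0) == 10000.0     # hold after last breakpoint
    assert s(0.05) == pytest.approx(2500.0)
    with pytest.raises(ValueError):
        ActivationSchedule("GGa", [(0.0, 0.0), (0.0, 1.0)])
    with pytest.raises(ValueError):
        ActivationSchedule("GGa", [(0.0, 0.0), (0.5, -3.0)])


# ----------------------------------------------------------- GG partition
@pytest.fixture(scope="module")
def phantom():
    return generate_tongue_phantom(PhantomSpec())


def _origin(phantom):
    spec = phantom.metadata["phantom_spec"]
    return (np.array([(spec["fan_origin_frac"][0] - 0.5) * spec["length"],
                      spec["fan_origin_frac"][1] * spec["height"], 0.0]),
            spec["tendon_height_frac"] * spec["height"])


def test_gg_partition_nonempty_disjoint_and_complete(phantom):
    origin, tendon_y = _origin(phantom)
    sets = build_genioglossus_partition(phantom, origin, tendon_y,
                                        sector_angles=(55.0, 100.0))
    region = np.unique(np.concatenate(
        [phantom.element_sets[n] for n in ("GGa", "GGm", "GGp", "GGh")]))
    ids = [set(s.element_ids.tolist()) for s in sets]
    for s in sets:
        assert len(s.element_ids) > 0
        assert np.abs(np.linalg.norm(s.fibers, axis=1) - 1).max() < 1e-12
    for i in range(4):
        for j in range(i + 1, 4):
            assert not (ids[i] & ids[j])
    assert set().union(*ids) == set(region.tolist())


def test_gg_partition_sector_rotation_moves_only_adjacent(phantom):
    """Rotating the first sector boundary moves elements only between GGp
    and GGm (adjacent sectors), never across non-adjacent sets."""
    origin, tendon_y = _origin(phantom)
    base = {s.name: set(s.element_ids.tolist())
            for s in build_genioglossus_partition(
                phantom, origin, tendon_y, sector_angles=(55.0, 100.0))}
    moved = {s.name: set(s.element_ids.tolist())
             for s in build_genioglossus_partition(
                 phantom, origin, tendon_y, sector_angles=(65.0, 100.0))}
    # growing GGp's sector can only take from GGm
    assert moved["GGp"] >= base["GGp"]
    assert base["GGm"] >= moved["GGm"]
    assert moved["GGp"] - base["GGp"] == base["GGm"] - moved["GGm"]
    assert moved["GGa"] == base["GGa"]
    assert moved["GGh"] == base["GGh"]


def test_gg_partition_errors(phantom):
    origin, tendon_y = _origin(phantom)
    with pytest.raises(ValueError):
        build_genioglossus_partition(phantom, origin, tendon_y,
                                     sector_angles=(100.0, 55.0))
    with pytest.raises(ValueError):
        build_genioglossus_partition(phantom, origin, tendon_y,
                                     region=np.array([], dtype=int))
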