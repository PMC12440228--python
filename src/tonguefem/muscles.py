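"""Muscle registry: activation schedules, phoneme preset tables, and the
4-unit functional partitioning of the Genioglossus.

The Genioglossus fans out mid-sagittally from the genial tubercle.  Its
horizontal fibers below the short quasi-horizontal tendon form the GGh;
the oblique fan above the tendon is split into three angular sectors —
posterior (GGp), medium (GGm) and anterior (GGa, reaching the apex).  The
sector boundary angles are free parameters (defaults 55 and 100 degrees
above the posterior horizontal); published models tuned them on /i/ imaging
data without reporting coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .constitutive import HillActivation
from .mesh import Mesh

PHONEMES = ("a", "u", "i", "t", "k")

#: default sigma_max when a muscle is never activated in the preset table
_SIGMA_MAX_FLOOR = 10_000.0  # Pa


def load_presets() -> dict:
    """The shipped phoneme preset tables (stress plateaus, jaw/hyoid data)."""
    with resources.files("tonguefem.data").joinpath(
            "phoneme_presets.yaml").open() as fh:
        return yaml.safe_load(fh)


_PRESETS = None


def _presets() -> dict:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = load_presets()
    return _PRESETS


def default_sigma_max(muscle: str) -> float:
    """Default maximal isometric stress: 1.2x the largest preset stress for
    the muscle, so schedule-derived activations stay <= 1/1.2."""
    table = _presets()["active_stresses_pa"]
    peak = max(row.get(muscle, 0.0) for row in table.values())
    return 1.2 * peak if peak > 0 else _SIGMA_MAX_FLOOR


@dataclass
class MuscleSet:
    """A muscle: element ids, per-element unit fibers, Hill parameters."""
    name: str
    element_ids: np.ndarray
    fibers: np.ndarray
    sigma_max: float = None
    hill: HillActivation = None

    def __post_init__(self):
        self.element_ids = np.asarray(self.element_ids, dtype=np.int64)
        self.fibers = np.asarray(self.fibers, dtype=float)
        if self.fibers.shape != (len(self.element_ids), 3):
            raise ValueError("fibers must be (n_elements, 3)")
        norms = np.linalg.norm(self.fibers, axis=1)
        if norms.size and np.abs(norms - 1.0).max() > 1e-12:
            raise ValueError("fiber vectors must be unit length")
        if self.sigma_max is None:
            self.sigma_max = default_sigma_max(self.name)
        if self.hill is None:
            self.hill = HillActivation(sigma_max=self.sigma_max)


def muscle_sets_from_mesh(mesh: Mesh, names=None) -> list[MuscleSet]:
    names = names or sorted(mesh.fiber_fields)
    return [MuscleSet(n, mesh.element_sets[n], mesh.fiber_fields[n])
            for n in names]


# ----------------------------------------------------------- schedules
@dataclass
class ActivationSchedule:
    """Piecewise-linear active-stress profile s(t) for one muscle (Pa)."""
    muscle: str
    breakpoints: list = field(default_factory=list)  # [(t_s, stress_pa), ...]

    def __post_init__(self):
        times = [t for t, _ in self.breakpoints]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(s < 0 for _, s in self.breakpoints):
            raise ValueError("stresses must be >= 0")
        if self.breakpoints and self.breakpoints[0][1] != 0.0 \
                and self.breakpoints[0][0] == 0.0:
            warnings.warn(f"schedule for {self.muscle} starts at a nonzero "
                          "stress (discontinuous loading)")

    def __call__(self, t: float) -> float:
        return evaluate_schedule(self, t)

    @property
    def plateau(self) -> float:
        return self.breakpoints[-1][1] if self.breakpoints else 0.0


def evaluate_schedule(schedule: ActivationSchedule, t) -> float:
    """Linear interpolation; constant extrapolation after the last breakpoint
    (and before the first)."""
    if not schedule.breakpoints:
        return 0.0
    times = np.array([p[0] for p in schedule.breakpoints])
    vals = np.array([p[1] for p in schedule.breakpoints])
    out = np.interp(t, times, vals)
    return float(out) if np.ndim(out) == 0 else out


def schedule_from_table(phoneme: str, ramp_s: float = 0.2,
                        hold_s: float = 0.8) -> list[ActivationSchedule]:
    """Ramp-and-hold schedules reaching the preset plateau stresses.

    One schedule per muscle with a nonzero preset stress; the plateau equals
    the table value exactly.  ``ramp_s = 0`` produces a step schedule and a
    warning (discontinuous loading).
    """
    table = _presets()["active_stresses_pa"]
    if phoneme not in table:
        raise KeyError(f"unknown phoneme {phoneme!r}; known: {PHONEMES}")
    out = []
    for muscle, stress in table[phoneme].items():
        if stress == 0:
            continue
        if ramp_s <= 0:
            warnings.warn(f"zero ramp for {muscle}: step (discontinuous) "
                          "activation schedule")
            bps = [(0.0, float(stress)), (hold_s, float(stress))]
        else:
            bps = [(0.0, 0.0), (ramp_s, float(stress)),
                   (ramp_s + hold_s, float(stress))]
        out.append(ActivationSchedule(muscle, bps))
    return out


def jaw_hyoid_displacements(phoneme: str) -> dict:
    """Preset jaw opening and hyoid displacement targets (mm)."""
    table = _presets()["jaw_hyoid_mm"]
    if phoneme not in table:
        raise KeyError(f"unknown phoneme {phoneme!r}; known: {PHONEMES}")
    return dict(table[phoneme])


# ----------------------------------------------- Genioglossus partition
def build_genioglossus_partition(mesh: Mesh, fan_origin, tendon_plane_y: float,
                                 sector_angles=(55.0, 100.0),
                                 region: str | np.ndarray = "GG") -> list[MuscleSet]:
    """Partition a Genioglossus region into GGh, GGp, GGm, GGa.

    Elements (by centroid) below the quasi-horizontal tendon plane and
    posterior to the fan origin form the GGh (horizontal backward fibers);
    the rest of the region is a fan from ``fan_origin``, split by angle
    above the posterior horizontal into GGp (up to the first sector angle),
    GGm (up to the second) and GGa (beyond, reaching the apex; fibers
    radiate from the origin).

    ``region`` is either the name of an element set or an array of element
    ids; by default the union of any existing GG* sets is used.
    """
    a1, a2 = sector_angles
    if not a1 < a2:
        raise ValueError("sector boundary angles must be ordered")
    origin = np.asarray(fan_origin, dtype=float)

    if isinstance(region, str):
        if region == "GG":
            ids = np.unique(np.concatenate(
                [np.asarray(mesh.element_sets[n])
                 for n in ("GGa", "GGm", "GGp", "GGh")
                 if n in mesh.element_sets]))
        else:
            ids = np.asarray(mesh.element_sets[region])
    else:
        ids = np.asarray(region, dtype=np.int64)
    if ids.size == 0:
        raise ValueError("empty Genioglossus region")

    cent = mesh.element_centroids()[ids]
    dx = cent[:, 0] - origin[0]
    dy = cent[:, 1] - origin[1]
    phi = np.degrees(np.arctan2(dy, -dx))

    ggh = (cent[:, 1] < tendon_plane_y) & (cent[:, 0] < origin[0])
    fan = ~ggh
    ggp = fan & (phi > 0.0) & (phi <= a1)
    ggm = fan & (phi > a1) & (phi <= a2)
    gga = fan & ((phi > a2) | (phi <= 0.0))

    out = []
    for name, mask in (("GGa", gga), ("GGm", ggm), ("GGp", ggp), ("GGh", ggh)):
        sel = ids[mask]
        if sel.size == 0:
            raise ValueError(f"empty Genioglossus sector {name}")
        if name == "GGh":
            fib = np.tile([-1.0, 0.0, 0.0], (sel.size, 1))
        else:
            d = cent[mask] - origin
            fib = d / np.linalg.norm(d, axis=1, keepdims=True)
            if name == "GGa":
                from .phantom import GGA_VERTICAL_BLEND
                fib[:, 1] += GGA_VERTICAL_BLEND
                fib /= np.linalg.norm(fib, axis=1, keepdims=True)
        out.append(MuscleSet(name, sel, fib))
    return out


def check_preset_consistency(phoneme: str) -> bool:
    """Nonzero preset muscles match the published activated-muscle sets
    for the cardinal vowels (GGp/GGh reported as one merged column)."""
    p = _presets()
    if phoneme not in p["activated_sets"]:
        raise KeyError(f"no activated-muscle record for {phoneme!r}")
    nonzero = {m for m, s in p["active_stresses_pa"][phoneme].items() if s > 0}
    merged = {("GGp/GGh" if m in ("GGp", "GGh") else m) for m in nonzero}
    return merged == set(p["activated_sets"][phoneme])
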