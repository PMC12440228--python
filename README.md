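# tonguefem

A soft-tissue finite-element simulator for tongue-like organs, built for
speech-articulation biomechanics: quadratic tetrahedral (TET10) meshes,
Yeoh hyperelastic passive tissue, Hill-type active muscle elements with up
to two fiber directions per element, quasi-static and transient
muscle-driven solvers, and the mesh-convergence methodology used to pick a
working mesh density against the ~1 mm accuracy of electromagnetic
articulography.

The package ships a **synthetic tongue phantom** — a parametric,
mirror-symmetric half-ellipsoid-like solid with a flat mouth-floor face, a
convex dorsum and an anterior apex — carrying element sets and unit fiber
fields for 12 muscles (the four functional Genioglossus units GGa, GGm,
GGp, GGh; Styloglossus; Hyoglossus; Verticalis; Transversalis; Inferior and
Superior Longitudinalis; Geniohyoid; Mylohyoid), four phonetic landmark
nodes (apical, alveolar, velar, pharyngeal) and bone-attachment node sets.
It is a geometric idealization, not a traced anatomy; it exists so that
every capability of the simulator can be exercised and tested without any
subject-specific imaging data.

## The model

Passive tissue follows a two-term Yeoh law with a quadratic volumetric
penalty,

    W = C10 (Ī₁ − 3) + C20 (Ī₁ − 3)² + K/2 (J − 1)²,

with Ī₁ = J^(−2/3) tr(FᵀF), J = det F, and the bulk modulus tied to the
Poisson ratio by K = 2 C10 / (1 − 2 ν).  The default tongue-tissue
parameters are C10 = 192 Pa, C20 = 90 Pa, ν = 0.49 (K = 19 200 Pa),
ρ = 1040 kg/m³.

A recruited muscle adds a uniaxial, tension-positive Cauchy stress along
its (deformed) fiber direction,

    σ_active = σ_max · a(t) · f_l(λ) · f_v(ε̇) · m ⊗ m,

with activation a ∈ [0, 1], a Gaussian force-length bell f_l centred on the
optimal fiber stretch, and a Hill force-velocity hyperbola f_v.  Elements
where two muscles interdigitate superimpose two such contributions.
Activation schedules are piecewise-linear fiber-stress profiles (Pa);
presets reproduce the published activation plateaus and jaw/hyoid
displacements for the five isolated French phonemes /a/, /u/, /i/, /t/,
/k/.

The solvers are total-Lagrangian TET10 finite elements with analytic
consistent tangents, Newton-Raphson with line search and load continuation
for statics, Newmark-β / backward-Euler with consistent mass and Rayleigh
damping for transients, linear spring attachments (1D cable stand-ins),
and frictionless penalty contact against rigid triangulated surfaces
(STL/OBJ).

## A worked example

```python
>>> from tonguefem.solver import apply_phoneme_preset, solve_phoneme_posture
>>> schedules, bc = apply_phoneme_preset("i")
>>> {s.muscle: s.plateau for s in schedules}
{'GGa': 3500.0, 'GGp': 4000.0, 'GGh': 10000.0, 'GH': 6000.0}
>>> mesh, res = solve_phoneme_posture("i")   # ~30 s on one CPU
>>> for lm, traj in res.landmark_trajectories.items():
...     print(lm, traj[-1].round(2))
landmark_apical [-1.99 -4.65  0.  ]
landmark_alveolar [-0.46 -7.12  0.  ]
landmark_velar [12.13 -1.31  0.  ]
landmark_pharyngeal [ 8.58 -1.2   0.  ]
```

The /i/ preset activates the anterior and posterior Genioglossus, its
horizontal bundle, and the Geniohyoid, and imposes the preset hyoid
(+5.8 mm front, −5.6 mm down) and jaw (3 mm opening) displacements.  The
landmark displacements (mm; X positive = front, Y positive = up) show the
tongue body carried forward — the velar and pharyngeal landmarks advance
by 9–12 mm, the expected high-front /i/ gesture on this phantom — while
the anterior Genioglossus grooves the blade and lowers the tip by ~5 mm
against the advancing body.

More narrative scripts live in `examples/`: phantom anatomy, constitutive
point tests, single-muscle effect maps, phoneme postures, mesh-convergence
studies and config-driven runs with manifests.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main pipeline from scratch —
phantom generation, mesh quality, a static gravity solve with landmark
displacements, and the constitutive closed-form checks — and writes a JSON
summary:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/tonguefem/` — mesh model, phantom, refinement, quality, I/O
  (Gmsh 4.1, VTU, JSON container, STL/OBJ), constitutive laws, muscles and
  presets, FE core, solvers, convergence tools, config runner
- `examples/` — one short script per capability
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — the model, numerical choices, and known limitations
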