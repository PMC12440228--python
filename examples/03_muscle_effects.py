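"""Single-muscle activation effects on the tongue phantom.

Activates one muscle at a time (2 kPa, static limit, gravity off) and
prints the displacement of the four phonetic landmarks.  The signs
reproduce the classical functional picture: the posterior Genioglossus
pushes the pharyngeal tongue forward, the anterior Genioglossus lowers the
apex with little effect on the dorsum, the Styloglossus elevates the velar
dorsum while retracting the apex, and the Hyoglossus pulls the body down
and back.
"""
import numpy as np

from tonguefem import (BoundaryConditions, PhantomSpec,
                       generate_tongue_phantom, muscle_sets_from_mesh,
                       solve_static)
from tonguefem.muscles import ActivationSchedule
from tonguefem.phantom import styloglossus_cables

spec = PhantomSpec(resolution=9.0, symmetric_half=True)
mesh = generate_tongue_phantom(spec)
muscles = muscle_sets_from_mesh(mesh)
bc = BoundaryConditions(
    fixed_sets=("floor_fixed", "hyoid_attachment", "mandible_attachment",
                ("midsagittal", (False, False, True))),
    gravity=(0.0, 0.0, 0.0),
    springs=list(styloglossus_cables(spec)))

for name in ("GGp", "GGa", "SG", "HG"):
    sched = [ActivationSchedule(name, [(0.0, 0.0), (0.2, 2000.0),
                                       (1.0, 2000.0)])]
    res = solve_static(mesh, muscles=muscles, bc=bc, schedules=sched,
                       load_scale_steps=2)
    print(f"\n{name} at 2 kPa — landmark displacements (mm, X front+, Y up+):")
    for lm in ("landmark_apical", "landmark_alveolar", "landmark_velar",
               "landmark_pharyngeal"):
        dx, dy, _ = res.landmark_final(lm)
        print(f"  {lm.replace('landmark_', ''):12s} dX={dx:+6.2f}  dY={dy:+6.2f}")
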