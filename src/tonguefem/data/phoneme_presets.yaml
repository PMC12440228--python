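# Phoneme presets for the five isolated French speech sounds.
#
# active_stresses_pa: plateau active stress per muscle (Pa) for each phoneme
#   (source model's published activation table, reproduced verbatim).
# jaw_hyoid_mm: mandibular opening (mm, applied as lowering of the mandible
#   attachment) and hyoid displacement (mm; X positive = front, Y positive
#   = up) for each phoneme.
# activated_sets: the set of muscles reported active per cardinal vowel in
#   the source model's cross-model comparison table ("C" entries); the
#   posterior/horizontal Genioglossus appears there as the merged column
#   "GGp/GGh".
active_stresses_pa:
  a: {GGa: 8000, GGm: 8000, GGp: 0, GGh: 2000, SG: 20000, HG: 3000,
      Vert: 0, Trans: 0, IL: 5000, SL: 0, GH: 0, MH: 0}
  u: {GGa: 0, GGm: 0, GGp: 0, GGh: 35000, SG: 90000, HG: 0,
      Vert: 0, Trans: 0, IL: 0, SL: 2000, GH: 10000, MH: 0}
  i: {GGa: 3500, GGm: 0, GGp: 4000, GGh: 10000, SG: 0, HG: 0,
      Vert: 0, Trans: 0, IL: 0, SL: 0, GH: 6000, MH: 0}
  t: {GGa: 15000, GGm: 10000, GGp: 2000, GGh: 5000, SG: 0, HG: 0,
      Vert: 500, Trans: 0, IL: 0, SL: 1300, GH: 0, MH: 5000}
  k: {GGa: 0, GGm: 0, GGp: 0, GGh: 6000, SG: 70000, HG: 0,
      Vert: 0, Trans: 0, IL: 0, SL: 0, GH: 2500, MH: 10000}
jaw_hyoid_mm:
  a: {jaw_opening: 11.0, hyoid_x: 0.8, hyoid_y: -0.9}
  u: {jaw_opening: 7.0, hyoid_x: 6.0, hyoid_y: -7.0}
  i: {jaw_opening: 3.0, hyoid_x: 5.8, hyoid_y: -5.6}
  t: {jaw_opening: 1.0, hyoid_x: 1.1, hyoid_y: 3.3}
  k: {jaw_opening: 5.0, hyoid_x: 2.7, hyoid_y: 5.2}
activated_sets:
  a: [GGa, GGm, GGp/GGh, SG, HG, IL]
  u: [GGp/GGh, SG, SL, GH]
  i: [GGa, GGp/GGh, GH]
# auxiliary structures: linear-elastic parameters (Pa, -, kg/m^3)
auxiliary_materials:
  hyoid_bone: {young_modulus: 1.1e10, poisson_ratio: 0.33, density: 2000}
  mandible: {young_modulus: 1.1e10, poisson_ratio: 0.33, density: 3600}
  maxilla: {young_modulus: 1.1e10, poisson_ratio: 0.33, density: 3600}
  hyoid_muscles: {young_modulus: 40000, poisson_ratio: 0.499, density: 1040}
  thyro_hyoid_membrane: {young_modulus: 10000, poisson_ratio: 0.49, density: 1040}
# tongue passive tissue (Yeoh)
tongue_material: {c10: 192.0, c20: 90.0, poisson_ratio: 0.49, density: 1040.0}
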