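# hrasim — femoral version and hip-resurfacing biomechanics, at desk scale

`hrasim` is a parametric simulation study of how femoral neck version
(anteversion/retroversion) and acetabular cup orientation affect a
metal-on-metal hip resurfacing arthroplasty (HRA) of the
Birmingham type.  It reproduces, with fast geometric and
discrete-element surrogates, the two analyses of a classic implant
positioning experiment:

1. **Impingement** — the femur (54 mm head, 42 mm neck, 125° neck-shaft
   angle, 20° native anteversion) is flexed 0–90° in the sagittal plane
   about the fitted center of rotation while a triangle-mesh collision
   query watches for the neck striking the cup rim or the peri-acetabular
   bone.  The output is the flexion angle of impingement onset and the
   impinging surface area.
2. **Bearing contact** — the conformal bearing (54 mm head in a cup with
   80 µm radial clearance) is modelled as an elastic foundation: a bed of
   independent compressive springs on the cup's inner surface, with element
   pressure `p_i = k·max(0, u·e_i − c)` for head-center displacement `u`,
   clearance `c` and foundation stiffness `k` (MPa/mm).  Newton iteration
   on `Σ p_i A_i e_i = F` gives the pressure field, peak pressure and
   contact area under the tabulated in-vivo loads (238 / 251 / 156 %BW at
   0° / 45° / 90° of hip flexion, reference weight 836 N).  Femoral version
   enters through the finite articular cap of the resurfacing head: at 90°
   of flexion with a retroverted femur the contact patch runs off the edge
   of the cap, concentrating pressure — the mechanism behind the
   retroversion effect.

The full experiment is a sweep over 5 femoral versions (+30…−30°) ×
4 cup poses (40/50° inclination × 15/25° version, radiographic angles) ×
3 load cases = 60 configurations.

## Worked example

```python
from hrasim import LOAD_CASES, contact_metrics
from hrasim.sweep import SweepConfig, SweepEngine

engine = SweepEngine(SweepConfig())          # builds meshes, calibrates k
onset, area90, octant = engine.impinge_one(-30.0, (40.0, 15.0))
print(onset, round(area90, 1), octant)       # 54.0 229.4 anterolateral

sol = engine.solve_one_contact(-30.0, (50.0, 15.0), LOAD_CASES["flex90"])
print(round(sol.peak_pressure, 3), round(sol.contact_area))   # 5.801 429
```

The 30°-retroverted femur with the cup at 40°/15° first impinges at 54° of
flexion, with ~229 mm² of anterolateral neck engaged by 90°; under the
sitting load with the cup at 50°/15° its peak bearing pressure is
5.80 MPa over a 429 mm² patch — an 8.7 % increase over the
neutral-version comparator (5.34 MPa, 506 mm²), with the patch shifted
toward the anterior bone–implant interface.

The numbered drivers under `analysis/` run the study end to end and write
tables/figures under `results/`:

```bash
python analysis/01_build_anatomy.py      # meshes + fitted COR
python analysis/02_impingement_sweep.py  # onset angles, area vs flexion
python analysis/03_contact_solve.py      # calibrated contact solves
python analysis/04_full_sweep_report.py  # all 60 configs, CSVs + figures
```

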