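# perfvec

Quantification of myocardial perfusion SPECT with the **perfusion vector**:
the displacement between the anatomical centroid of the left-ventricular
mid-myocardial surface and its perfusion-weighted centre of gravity. A single
localized perfusion defect pulls the centre of gravity away from the defect,
so the vector's direction encodes the defect's location and its magnitude
grows with defect severity and extent — one compact, orientation-aware
statistic per study instead of a segmental score.

The package is aimed at nuclear-cardiology method developers: it bundles the
statistic itself, a digital left-ventricle phantom for controlled experiments
(parameterised defects, SPECT-like blur and Poisson noise), a
volume-to-surface intensity sampler, and the nonparametric statistics
pipeline used to validate vector metrics on cohorts.

## The statistic

The mid-myocardial surface is a grid of rectangles, each with index *i*,
centre (*x*ᵢ, *y*ᵢ, *z*ᵢ) in mm, area *A*ᵢ, and intensity weight *W*ᵢ. The
weighted centroid is

```
C = ( Σ xᵢ Aᵢ Wᵢ / Σ Aᵢ Wᵢ ,  Σ yᵢ Aᵢ Wᵢ / Σ Aᵢ Wᵢ ,  Σ zᵢ Aᵢ Wᵢ / Σ Aᵢ Wᵢ )
```

With *W*ᵢ = 1 this is the anatomical centroid **C**_A; with *W*ᵢ set to the
measured tracer intensity it is the perfusion centre of gravity **C**_P. The
perfusion vector is

```
P = C_P − C_A
```

reported per axis and as the magnitude ‖**P**‖. Stress/rest studies are
compared by |**P**ₛ| − |**P**ᵣ| (the headline difference metric) and by
‖**P**ₛ − **P**ᵣ‖.

### Cardiac frame and angular convention

```
          anterior (θ = 270°)
              −y
               |
 septal ------ o ------ lateral      +x : septal → lateral
 (θ=180°) −x   |   +x   (θ = 0°)     +y : anterior → inferior
               |                     +z : basal → apical
              +y
          inferior (θ = 90°)
```

θ is measured in the short-axis (x–y) plane from +x toward +y. With these
signs, an anterior defect pushes **P** toward +y (the y component increases)
and a lateral defect pushes it toward −x (the x component decreases).

## Worked example

```python
import perfvec as pv
from perfvec.phantom import AcquisitionSpec, DefectSpec
from perfvec.sampling import sample_weights

# 148-mL ventricle, 50-degree anterior defect, 7-mm blur, no noise
shape = pv.LVShapeSpec()                       # solved to 148 mL cavity
acq = AcquisitionSpec(noise=False)
defect = DefectSpec("anterior", alpha_deg=50.0)

vol, grid = pv.simulate_study(shape, defect, acq)
weights = sample_weights(vol, grid)
result = pv.compute_perfusion_vector(grid, weights, phase="stress")
print([round(v, 2) for v in result.vector], round(result.magnitude, 2))
```

prints

```
[-0.0, 3.59, 0.65] 3.65
```

The defect sits anteriorly (−y side), so the vector points away from it with
a +3.59 mm y component; the x component is zero by symmetry and the z
component stays small. Repeating with `alpha_deg` 10/30/50/70 gives y
components 0.79 / 1.94 / 3.59 / 5.01 mm — the magnitude tracks defect size.

The same pipeline is available from the shell:

```
perfvec simulate --defect-location anterior --defect-angle 50 --seed 7
perfvec vector --surface surface.csv
perfvec cohort --n-normal 40 --n-per-group 20 --seed 1 --out cohort.csv
perfvec stats --table cohort.csv --metric stress_mag --reference normal
```

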