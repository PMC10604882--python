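# tavi4d

Automatic geometric analysis of transcatheter aortic valve (TAVI)
prostheses and the surrounding aortic root in ECG-gated 4D cardiac CT.

After TAVI, the stented valve moves and deforms with every heartbeat.
Quantifying that behavior — how the frame expands, tilts, and travels, and
how much free lumen remains between device and aortic wall at each level —
is useful to cardiologists and imaging researchers studying device
anchoring, paravalvular leak risk, and patient–prosthesis mismatch.
`tavi4d` extracts these quantities fully automatically from a multi-phase
CT study, one 3D volume per cardiac phase.

## Method

Per phase `t` the pipeline runs:

1. **Frame segmentation.** Metal struts are far brighter than
   contrast-filled blood: threshold at `Th1` (default 800 HU), drop
   connected components smaller than `Th2` voxels (default 11,000 at
   ~0.65 × 0.65 × 0.56 mm voxels), then reject dense solid structures
   (calcifications) by their *fill fraction* — component voxels over
   solidified-hull voxels — keeping the least dense, thread-like
   component: the wireframe.
2. **Filling segment.** The frame's largest internal cavity is solidified
   (morphological sealing of the strut cells, capping of the tube mouths,
   flood fill). Its volume is the prosthesis inner volume `V(t)`.
3. **Principal axis & reformat.** The filling's principal inertia axis
   gives the device director `v`. With `θ = arccos(v·ẑ)` and
   `n = v × ẑ / |v × ẑ|`, the study is rotated about its center by `θ`
   around `n` (Rodrigues), so image planes become orthogonal to the
   device.
4. **Aortic-root segmentation.** Two automatic seeds — a sphere of radius
   `R1` voxels at the filling centroid (lumen) and a circle of radius `R2`
   voxels around the frame's center of mass, in the plane orthogonal to
   the axis (background) — compete on the voxel graph under an
   intensity-difference path cost (multi-source Dijkstra). Post-processing
   removes protrusions, strips coronary-caliber side branches, and
   median-smooths the surface.
5. **Metrics.** `V(t)`; center of mass `c(t)`; axis angles `α(t)`;
   displacement `d(t) = |c(t) − c(t−1)|`; cross-sectional areas
   `CSA_p(t, h)` and `CSA_a(t, h)` along the normalized height `h`
   (0% = outflow tip, 100% = inflow/annulus tip); and the implant gap
   `dCSA = CSA_a − CSA_p`. Analysis planes: `h1` (outflow), `h2` (maximum
   device diameter; `h2 = h1` for outflow-maximal frames), `h3` (inflow).
   Cohort tables aggregate mean ± sample SD per device model.

Patient studies are read from DICOM series or per-phase NIfTI volumes.
Because clinical data cannot ship with the package, a phantom module
generates synthetic 4D studies — a bright diamond-lattice wireframe inside
a contrast lumen, with optional speckles, calcification, coronary-like
branch, per-phase motion and expansion — with full analytic ground truth.

## Worked example

```python
import numpy as np
from tavi4d import PhantomSpec, PipelineConfig, generate_phantom, run_pipeline

spec = PhantomSpec(
    grid_shape=(96, 96, 96), spacing=(0.6, 0.6, 0.6),
    frame_radius_mm=10.0, frame_length_mm=30.0, lumen_radius_mm=14.0,
    tilt_deg=12.0, n_phases=2, seed=0,
)
study, truth = generate_phantom(spec)
res = run_pipeline(study, PipelineConfig(th2=1000), patient_id="demo")

st, p = res.states[0], res.profiles[0]
print(f"inner volume V(0)        = {st.V:9.1f} mm^3")
print(f"tilt angle theta(0)      = {np.degrees(res.axes[0].theta):9.2f} deg")
print(f"CSA_p(0, h=50%)          = {p.at(50.0):9.1f} mm^2")
print(f"dCSA(0, h=50%)           = {p.at(50.0, 'dcsa'):9.1f} mm^2")
print(f"analysis planes h1/h2/h3 = {res.planes.h1:.0f} / {res.planes.h2:.0f} / {res.planes.h3:.0f} %")
```

prints

```
inner volume V(0)        =    9356.3 mm^3
tilt angle theta(0)      =     12.04 deg
CSA_p(0, h=50%)          =     321.8 mm^2
dCSA(0, h=50%)           =     292.3 mm^2
analysis planes h1/h2/h3 = 0 / 0 / 100 %
```

i.e. the device volume is recovered within ~1% of the analytic
π·10²·30 = 9424.8 mm³, the 12° implantation tilt within 0.05°, the
mid-height device area within ~2.5% of π·10² and the device-to-wall gap
within ~3% of the analytic annulus π(14² − 10²); a constant-radius frame
reports `h2 = h1 = 0` by convention. (`th2` is rescaled to 1000 voxels
here because the phantom wireframe is thinner than a clinical
blooming-inflated frame.)

The same pipeline is scriptable from the shell:

```sh
tavi4d phantom --out-dir ph/ --phases 2
tavi4d run --study ph/ --th2 1000 --out-dir out/
```

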