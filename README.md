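# spindlequant

Quantification of mitotic-spindle architecture and dynamics from multi-channel
fluorescence z-stacks, built for studies of how microtubule bundles — k-fibers,
bridging fibers and astral microtubules — are organized in bipolar spindles and
how their loss (for example after depletion of the augmin/HAUS nucleation
complex) degrades chromosome segregation.

It is intended for cell-biology labs doing live-cell confocal or STED imaging
of spindles who today do these measurements with ad-hoc ImageJ/MatLab/R
scripts: the package reimplements that analysis chain as a tested Python
library plus a `spindlequant` CLI, and pairs it with a synthetic-spindle
generator so every measurement can be validated against planted ground truth.

## What it measures

**Ratiometric microtubule counting** (`fiber_quant`). Background-subtracted
tubulin intensities of fiber ROIs are converted to microtubule numbers with
the k-fiber calibration

    n_b = I_b · n_k / I_k,      n_k = 12.6 microtubules,

where `I_b` and `I_k` are bridging- and k-fiber intensities (square-ROI or
line-profile scheme, the latter with `I_k = I_bk − I_b` from a pooled contour
profile). Astral microtubules (`n_a ≈ 1`) serve as a single-microtubule sanity
check of the calibration. A depletion summary closes the bookkeeping between
control and depleted populations (percent reduction, remaining and
nucleator-dependent counts).

**3D kinetochore geometry** (`kc_geometry`). Interkinetochore distances,
distances from the pole-to-pole axis `c = √(a² + b²)` and sister-axis tilt are
computed in corrected coordinates, with axial offsets multiplied by
`z_step × 0.81` to undo the depth compression of an oil objective imaging an
aqueous sample. Includes inner/outer region classification (cell-mean rule in
metaphase, normalized-0.5 rule in anaphase) and sub-voxel punctum localization
with mutual-contribution removal for sister pairs.

**End-on reslicing and bundle counting** (`end_on_view`). The side-view stack
is permuted so the viewing axis coincides with the spindle axis,
`I'(i·px, j·px, k·zd) = I(k·zd, i·px, j·px)`, with the axial coordinate
rescaled by 0.81 and resampled to the pixel pitch; bundles appear as discrete
spots in sum projections of central slices and are counted by prominence-
filtered peak detection.

**Bundle shape** (`bundle_shape`): least-squares circle fits (algebraic seed,
geometric refinement) and contour lengths of 10-point bundle traces.
**Kinetics** (`dynamics`): poleward flux from photoactivation-mark-to-pole
distances, anaphase A/B speeds from OLS slopes, onset detection from sustained
interkinetochore-distance rises. **Segregation errors** (`error_classify`):
misaligned / lagging / other classification of anaphase trajectories and
missegregation scoring. **PRC1 overlaps** (`overlap_quant`): overlap length as
the base of the PRC1 intensity peak, total PRC1 signal, relative overlap.

**Synthetic spindles** (`synthetic_spindle`). Ground-truth models (poles,
kinetochore pairs, fiber arcs with planted microtubule numbers) rendered into
calibrated noisy stacks: linear photometry, anisotropic Gaussian PSF, Poisson +
read noise, and axial placement at `z/(0.81 · z_step)` so the 0.81 correction
round-trips exactly. Also generates anaphase trajectories with planted
segregation errors and photoactivation time series with planted flux speeds.

## Worked example

```python
from spindlequant import fiber_quant as fq
from spindlequant.experiments import astral_calibration_experiment

# close the depletion bookkeeping from the measured counts
out = fq.depletion_summary(control_n_b=[3.8], control_n_k=[12.6],
                           depleted_n_b=[1.2], depleted_n_k=[9.6])
print({k: round(v, 1) for k, v in out.items()})

# recover the single-microtubule astral calibration on rendered STED phantoms
df = astral_calibration_experiment(n_spindles=30, seed=1)
print(f"mean n_a over {len(df)} astral fibers: {df['n_a'].mean():.3f}")
```

prints

```
{'percent_reduction_bridging': 68.4, 'n_b_remaining': 1.2, 'n_b_augmin': 2.6,
 'percent_reduction_k': 23.8, 'n_k_remaining': 9.6, 'n_k_augmin': 3.0}
mean n_a over 90 astral fibers: 1.000
```

i.e. bridging fibers lose 68% of their signal (3.8 → 1.2 microtubules, 2.6 of
them nucleator-dependent), k-fibers 24% (12.6 → 9.6, 3.0 dependent), and
fibers rendered with one microtubule are measured as 1.00 ± noise — the
ratiometric calibration is self-consistent end to end.

Or from the shell:

```bash
spindlequant run --seed 2 --outdir runs/demo   # simulate -> quantify -> summary
spindlequant simulate --seed 5 --outdir runs/sim
spindlequant geometry --annotations points.csv --out geometry.csv
```

## Documentation

`docs/methods.md` describes the models, parameter choices, noise defaults,
numerical conventions and known limitations.
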