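# dwiqc

Acquisition-time quality control for fetal diffusion MRI, at desk scale:
per-volume motion/quality features from brain masks, green/red volume
verdicts (slice dropout, b-value-dependent volume-change thresholding,
FOV cropping), prioritized re-acquisition planning with an iterative
merge loop, a synthetic phantom generator for end-to-end testing, and
voxel-wise ADC / IVIM fitting with ROI statistics.

## Concepts

A run consumes a 4D diffusion series (NIfTI), a matching 4D binary
brain-mask series (one mask per volume, normally from an external
segmentation tool), and an FSL-style bval/bvec pair. Each volume is
classified **green** or **red**:

- **dropout** — a slice whose mean in-mask intensity falls more than
  35% below the in-mask volume mean;
- **volume change** — |V − V_ref| / V_ref exceeding
  `alpha·(1 − e^(−b·ADC_ref)) + f` (defaults α = 0.3, f = 0.02,
  ADC_ref = 0.002 mm²/s), so high-b volumes tolerate the segmentation
  shrinkage caused by fluid signal attenuation;
- **cropping** — mask voxels touching the FOV boundary.

Red volumes are ranked into a re-acquisition plan (TSV manifest +
bval/bvec pair restricted to the planned volumes); re-acquired volumes
are merged back in place, for at most two iterations by default. The
inter-volume center-of-mass L2 trace is computed and reported but does
not by itself trigger re-acquisition.

## CLI

```sh
dwiqc simulate --config phantom.yaml --seed 7 --out-dir sim/
dwiqc qc --dwi sim/dwi.nii.gz --bval sim/dwi.bval --bvec sim/dwi.bvec \
         --mask sim/masks.nii.gz --out-dir qc/
dwiqc plan --report qc/report.json --bval sim/dwi.bval --bvec sim/dwi.bvec \
           --iteration 1 --out-dir plan/
dwiqc merge --dwi sim/dwi.nii.gz --bval sim/dwi.bval --bvec sim/dwi.bvec \
            --reacq-dwi reacq.nii.gz --reacq-bval r.bval --reacq-bvec r.bvec \
            --plan qc/reacq_plan.tsv --out-dir merged/
dwiqc iterate --dwi ... --mask ... --reacq-dir staged/ --out-dir it/
dwiqc fit adc  --dwi ... --bval ... --bvec ... --mask brain.nii.gz --out-dir maps/
dwiqc fit ivim --dwi ... --bval ... --bvec ... --mask brain.nii.gz --out-dir maps/
dwiqc sweep-alpha --dwi ... --mask ... --truth sim/truth.json \
                  --alphas 0.1:0.5:0.05 --out-dir sweep/
```

Every command writes a `run_manifest.json` beside its outputs;
validation errors exit with code 2. QC parameters come from a YAML
config (`--config`) mirroring `dwiqc.io_bridge.QCConfig`.

The phantom YAML accepts `grid`, `voxel_size`, `brain_semiaxes_mm`,
`csf_rim_mm`, `noise_sigma` (Rician sigma relative to parenchyma S0)
and an `artifacts` list, e.g.:

```yaml
grid: [64, 64, 35]
noise_sigma: 0.05
artifacts:
  - {kind: dropout_slices, volume: 3, slices: [10, 11], attenuation: 0.1}
  - {kind: com_shift, volume: 5, shift_mm: [3.0, -6.0, 0.0]}
  - {kind: volume_drift, volume: 8, rel_change: -0.10}
```

## Tests and acceptance report

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes four headline quantities from scratch
(reference-cohort ROI decrease count, the threshold value at b = 0 and
its limiting increment, and the bisected slice-rule boundary) and
writes them as JSON.
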