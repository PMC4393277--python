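# irmap

Model-based iterative reconstruction of quantitative T1 maps from a single
globally inversion-prepared, golden-angle radial Look-Locker (IR-LL) MRI
acquisition — about 6 s of data (1000 projections, 128 readout points) for a
full single-slice T1 map.

The reconstruction grids every radial projection onto its own time frame's
Cartesian k-space and then iterates a fixed number of times:

1. inverse DFT of the current model k-spaces into image space,
2. phase-sensitive multi-coil combination (per-coil realification with tail
   phase maps, sign-dependent sum of squares),
3. model enforcement: per-pixel orthogonal matching pursuit over a 740-atom
   dictionary of IR-LL relaxation curves spanning 185 T1 values
   (10–5000 ms) and flip angles 3/5/7/9°, limited to 3 atoms,
4. least-squares re-separation into per-coil model images, forward DFT,
5. data consistency: measured values overwrite the model on acquired cells.

After the final iteration a pixel-wise three-parameter mono-exponential fit
of `M(t) = M0* − (M0 + M0*) exp(−t/T1*)` yields `T1*`, `M0*`, `M0`, and the
flip-angle-independent `T1 = T1* · M0 / M0*`.

The package also provides the segmented fully-sampled IR-LL reference
reconstruction, a gold-standard inversion-recovery fit, ROI statistics
(mean / std / SNR), and a synthetic-acquisition simulator (seven-vial and
brain-like digital phantoms, smooth coil sensitivities, exact nonuniform-DFT
forward model, optional segmented acquisitions with incomplete-recovery
effects).

## Layout

| module               | contents                                                        |
| -------------------- | --------------------------------------------------------------- |
| `irmap.relaxometry`  | closed-form IR-LL physics (`T1*`, `M0*`, signal model, recovery) |
| `irmap.radial`       | golden-angle trajectory, per-frame gridding, centered unitary DFT, temporal interpolation init, data consistency |
| `irmap.coils`        | tail phase maps, realification, sign-dependent SoS, coil re-separation |
| `irmap.dictfit`      | dictionary construction, batched OMP, mono-exponential fitting  |
| `irmap.pipeline`     | the full iteration, segmented reference, gold standard, ROI stats |
| `irmap.simulate`     | digital phantoms, coil sensitivities, forward simulation        |
| `irmap.protocols`    | full-scale simulated validation studies                         |
| `irmap.io` / `irmap.cli` | HDF5 acquisition container, NIfTI/CSV export, command line  |

## CLI

```sh
irmap simulate --phantom vials --grid-side 128 --projections 1000 \
      --noise-sigma 0.01 --seed 1 --out acq.h5 --truth-out truth.nii.gz
irmap reconstruct acq.h5 --iterations 50 --out maps.nii.gz
irmap reference seg_acq.h5 --out ref.nii.gz
irmap roistats maps.nii.gz truth.nii.gz --out stats.csv
```

Acquisitions live in a small HDF5 container (`/samples`, `/angles`, `/ti`,
`/segment` + sequence attributes); parameter maps are written as 4D NIfTI
(T1, T1*, M0*, M0, valid, residual); ROI tables as CSV. Every CLI run
writes a JSON provenance sidecar.

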