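# retinakit

Quantitative analysis of labeled retinal ganglion cell (RGC) populations:

- **mosaic** — nearest-neighbor statistics, the regularity index
  (mean NND / SEM by default, with the classical mean/SD variant), the
  density recovery profile (DRP) with a 7th-order polynomial fit and a
  bootstrap 99% confidence band, and normalized density maps.
- **straighten** — flattening of curved retinal cross-sections with a
  bilinearly blended Coons patch spanned by the two nuclear-stain-derived
  IPL boundaries, plus normalized depth profiles (0% = GCL border,
  100% = INL border).
- **morphology** — SWC morphometry (total neurite length, branch points,
  dendritic stratification distribution) and classification into four
  stratification subtypes (bistratified S2+S4, mono ON S4, mono ON S5,
  mono OFF S1).
- **ephys** — spike-train metrics: firing adaptation index
  (`1 − T_last/T_initial`, plus a sign-flipped `decay_positive` variant),
  F-I curves, ON/OFF/ON-OFF flash classification, spot-size tuning, and
  direction tuning with a vector-sum direction selectivity index.
- **synth** — seeded generators for every input class (Poisson /
  hard-core / jittered-lattice mosaics, adapting and tuned spike trains,
  mono/bistratified morphologies, curved sections with known band
  depths), each artifact carrying its ground-truth record.
- **io / config / pipeline / cli** — CSV/SWC/TIFF readers and writers,
  validated run configuration, and an end-to-end synthetic report.

## Command line

```sh
retinakit --seed 1 simulate --kind hardcore --out points.csv
retinakit regularity points.csv --ri-mode sem
retinakit drp points.csv --dr 10 --rmax 200 --edge buffer --out drp.csv
retinakit --seed 1 simulate --kind section --out section.tiff
retinakit straighten section.tiff --nuclear-channel nuclear --out flat.tiff
retinakit stratify section.tiff --channel band0 --out profile.csv
retinakit --seed 1 simulate --kind morphology --out cell.swc
retinakit morph cell.swc --out features.csv
retinakit --seed 1 report        # full synthetic end-to-end bundle
```

Global flags `--config <yaml>`, `--seed`, `--verbose` precede the
subcommand; per-module defaults live in `retinakit.config.DEFAULTS` and
unknown config keys are rejected.

## Conventions

Coordinates and distances are μm (densities cells/mm²), times are
seconds, and IPL depth runs from 0% at the GCL border to 100% at the INL
border; strata S5…S1 tile that axis in equal quintiles with S5 adjacent
to the GCL (so ON strata S4/S5 sit at low depth, OFF strata S1/S2 at
high depth). All generators take explicit seeds; there is no hidden
global random state.
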