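# diadeconv

Spectrum-centric deconvolution of diaPASEF-style LC-IMS-MS data into
DDA-like pseudo-MS/MS spectra.

The pipeline detects precursor and fragment features in three dimensions
(m/z, retention time, inverse ion mobility 1/K0), groups MS1 features into
isotope envelopes with charge states, correlates fragment XICs with their
precursor inside the matching isolation window, and writes the assembled
spectra as centroided, indexed mzML that conventional database search
engines can consume. A bundled synthetic diaPASEF simulator with ground
truth makes every stage testable without vendor data.

## Layout

| module | role |
| --- | --- |
| `diadeconv.run_model` | in-memory run representation; open text fixture format (read/write/validate); window lookup; `FrameSource` backend protocol for future vendor adapters |
| `diadeconv.pasef_sim` | synthetic run generator (3D Gaussian species, isotope envelopes via averagine, co-eluting + decoy fragments, uniform chemical noise) and ground-truth manifest |
| `diadeconv.feature_detect` | per-window binning to an N×W grid, RT-frame aggregation, neighbor denoising, 2D Gaussian smoothing, local-maxima seeding, separable Gaussian fitting |
| `diadeconv.xic_trace` | frame-to-frame peak linking into XICs, apex/boundary logic, Savitzky-Golay + rolling Z-score segmentation of elongated peaks |
| `diadeconv.isotope_group` | MS1 isotope clustering (C13 spacing rule), envelope/XIC correlation scoring, charge assignment |
| `diadeconv.pseudo_msms` | optional fractional-mass filter, precursor-fragment Pearson gating, RF-max capping, spectrum assembly + provenance sidecar |
| `diadeconv.mzml_out` | deterministic indexed mzML 1.1 writer (stdlib only), MGF export, reader for round trips |
| `diadeconv.cli` | `simulate` / `deconvolute` / `validate-fixture` subcommands, flat config files, run logs |

## CLI

```sh
# generate a synthetic run + ground-truth manifest
diadeconv simulate --seed 1 --n-species 50 --out run.tsv --manifest truth.tsv

# check any fixture against the format invariants
diadeconv validate-fixture run.tsv

# deconvolute into pseudo-MS/MS spectra
diadeconv deconvolute --input run.tsv --output-prefix out \
    --min-seed-intensity 30 \
    --corr-threshold 0.3 --rf-max 500 --delta-apex-im 0.02 --delta-apex-rt 3
```

`deconvolute` writes `out.mzML` (indexed, centroided MS2), `out.sidecar.tsv`
(one provenance row per spectrum), `out.config` (every effective parameter;
feed it back via `--config` to reproduce a run bit-for-bit) and `out.log`.
Output is byte-deterministic for a fixed input/config, independent of the
`--threads` worker count.

Defaults for the assembly stage: `Corr threshold` 0.3, `RF max` 500,
`Delta Apex IM` 0.02, `Delta Apex RT` 3 s; the fractional `Mass Defect
Filter` is off by default (not recommended for PTM or nonspecific
workflows).

## Fixture format

A single UTF-8 text file, line-oriented, tab-separated, with a versioned
header and four record types:

```
#diadeconv-fixture	1
#meta	mz_step	0.02            # smallest m/z difference between signals
#meta	im_step	0.002           # smallest 1/K0 difference
W	<window_id>	<mz_low>	<mz_high>	<im_low>	<im_high>	<cycle_position>
F	<frame_id>	<rt_seconds>	<ms_level>	<im_lo>:<im_hi>:<window_id>[;...]
P	<frame_id>	<mz>	<inv_k0>	<intensity>
```

All floats are serialized with full `repr` precision, so read∘write is the
identity. Intervals are half-open `[low, high)`; points are sorted by
`(inv_k0, mz)`; MS2 points must fall inside exactly one window segment of
their frame.
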