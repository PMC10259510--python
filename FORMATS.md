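# File formats

All tabular outputs are plain CSV with a header row; configs are YAML;
manifests and summaries are JSON; movies are multi-page 16-bit TIFF.

## Plant trajectory CSV (`tifm simulate`)

| column          | unit | meaning                                   |
|-----------------|------|-------------------------------------------|
| time_s          | s    | simulation time                           |
| X_C_true_um     | µm   | ground-truth chip (holder) position       |
| X_T_true_um     | µm   | ground-truth tip position                 |
| C1_pF, C2_pF    | pF   | capacitor-pair readings (noisy)           |
| voltage_V       | V    | commanded piezo voltage                   |
| sigma_a_Pa      | Pa   | current tissue active-stress capacity     |
| tissue_front_um | µm   | tissue front position                     |

## Calibration table CSV (`tifm calibrate`)

`delta_C_pF` (capacitance difference C1−C2), `position_um` (imaged chip
position). Strictly monotone; valid only inside its range.

## Experiment record CSV (`tifm measure`, `tifm load`)

| column        | unit | meaning                                          |
|---------------|------|--------------------------------------------------|
| time_s        | s    | master-clock time of the imaging tick            |
| delta_C_pF    | pF   | inner-loop capacitance difference                |
| voltage_V     | V    | commanded piezo voltage                          |
| X_C_est_um    | µm   | chip position from the calibration table         |
| X_T_meas_um   | µm   | tip position from imaging/localization           |
| deflection_um | µm   | X_T_meas − X_C_est                               |
| F_nN          | nN   | k·deflection (exactly, by construction)          |
| sigma_Pa      | Pa   | F/A (exactly, by construction)                   |

Sidecar `<name>.json`: events `[{time_s, event}]`, config snapshot, seeds,
quality flag. Events include `insertion`, `stall_detected`,
`voltage_saturation`, `setpoint_saturation`, `tracking_quality_fail`.

## Tracked trace CSV (`tifm track`)

`time_s`, `X_T_um` (NaN on lost frames), `confidence` (0–1; 0.5 marks
gap-bridged frames), `lost` (bool).

## Cell track CSV

`cell_id`, `t_s`, `x_um` (axial), `y_um` (medial→lateral, positive =
lateral-ward), `label` (`loaded` | `control`). Nominal 5-min spacing.

## Movie TIFF (`tifm render`)

Multi-page 16-bit grayscale, one stack per channel. Sidecars:
`<name>.truth.csv` (`time_s`, `X_T_true_um` ground truth per frame) and
`<name>.meta.json` (pixel size, channel, imaging depth, probe and optics
parameter snapshots).

## Scenario YAML

Canonical form (sorted keys) produced by `ScenarioConfig.to_yaml()`;
loading and re-saving is byte-identical. Sections: `probe`, `piezo`,
`tissue`, `optics`, `control`, plus scalars (`contact_area_um2`,
`duration_s`, `force_target_nN`, …) and the `seeds` mapping. Unknown or
missing keys are rejected with a message listing the valid keys.

## Run manifest JSON

`config_hash` (SHA-256 of the canonical YAML), `scenario`, `seeds`,
`software_version`, `files` (name → SHA-256).
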