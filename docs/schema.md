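# Cell-table schema

One CSV row per segmented cell.  Required columns:

| column    | type  | meaning                                   |
|-----------|-------|-------------------------------------------|
| `cell_id` | int   | unique within a sample                    |
| `x_um`    | float | centroid x, µm (image convention, origin top-left) |
| `y_um`    | float | centroid y, µm (y increases downward)     |

Per-marker columns for the panel
`CD3, CD4, CD8, PD1, PDL1, FOXP3, CD68, CKSOX10, NOS2, COX2, IFNG, IDO1, B7H4`:

| column       | type  | meaning                                    |
|--------------|-------|--------------------------------------------|
| `<M>_int`    | float | marker intensity (arbitrary units)         |
| `<M>_pos`    | bool  | generator ground-truth positivity (synthetic data only) |
| `<M>_call`   | bool  | gated positivity (`phenotyping.call_positivity`) |

Columns added by the pipeline:

| column            | producer                       | values |
|-------------------|--------------------------------|--------|
| `phenotype`       | `phenotyping.assign_phenotypes`| Tumor, Macrophage, CD8_TReg, TEx, TEff, CD4_TReg, CD4_T, Other |
| `is_tumor`, `is_leukocyte` | assign_phenotypes     | bool |
| `nos2_grade`      | assign_phenotypes              | "", weak, medium, strong (tumor cells) |
| `nos2s`           | assign_phenotypes              | bool, strong stratum (or medium+strong via panel switch) |
| `tumor_cox2`, `tumor_pdl1`, `mac_pdl1`, `mac_cox2` | assign_phenotypes | bool sub-flags |
| `region`          | `regions.assign_cell_regions`  | lymphoid_aggregate, nos2pos_edge, nos2neg_edge, core, satellite, stroma |
| `region_nest_id`  | assign_cell_regions            | nest id or −1 |

Generator ground-truth columns (synthetic data only): `true_phenotype`,
`true_nos2_grade`, `nest_id`, `compartment_true`.

Unknown columns are preserved by `io.read_cell_table` / `io.write_cell_table`.

Cohort metadata CSV: `sample_id`, `group` (deceased/alive), `time_months`,
`event` (1 = death observed, 0 = censored).

Region maps serialize to GeoJSON: one feature per region with `label`
(nest / edge / core / satellite / lymphoid_aggregate) plus attributes
(`nest_id`, `area_mm2`, `nos2_status`, `nos2_fraction`, `thin`) in
`properties`.
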