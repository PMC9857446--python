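# Registry column dictionary

Two plain UTF-8 CSV tables with header rows, linked by `patient_id`.
Booleans are written as `0`/`1`; missing numeric values are empty fields
(never 0). See `fertiopt.core_registry` for the enforcing validators.

## `retrievals.csv` — one row per oocyte-retrieval (stimulation) cycle

| column | type | description |
| --- | --- | --- |
| `patient_id` | str | Opaque patient identifier. |
| `cycle_index` | int | 1 = first stimulation cycle, in treatment order. |
| `cycle_year` | int | Calendar year the cycle started. |
| `age_years` | float | Age at cycle start; study range 18–45. |
| `age_group` | str | One of `<32`, `32-34`, `35-37`, `38-40`, `41-42`, `>42`; must be consistent with `age_years` (intervals [18,32), [32,35), [35,38), [38,41), [41,43), [43,45]). |
| `region` | str | Categorical clinic region label (e.g. `R00` … `R07`). |
| `amh_ng_ml` | float? | Latest anti-müllerian hormone, ng/mL; empty if not measured. Banded as `unknown` / `<1` / `1-<4` / `>=4` for modelling. |
| `dor` | bool | Diminished-ovarian-reserve diagnosis. |
| `icsi` | bool | Intracytoplasmic sperm injection cycle. |
| `n_oocytes_retrieved` | int | Non-negative; ≥ 1 for eligible cycles. |
| `donor_oocyte` | bool | Exclusion flag. |
| `gestational_carrier` | bool | Exclusion flag. |
| `pgt` | bool | Preimplantation genetic testing; exclusion flag. |
| `transfer_day_label` | str | `day5` (transfer or freeze on day ≥ 5), `day3` (day 2–4), or `none` (no labelled embryo outcome). |
| `n_blastocysts_frozen` | float? | Defined only for `day5` cycles; empty otherwise. Never exceeds `n_oocytes_retrieved`. |
| `bmi` | float? | Optional descriptive field. |
| `gravidity` | float? | Optional descriptive field. |
| `fsh_miu_ml` | float? | Optional descriptive field. |

## `transfers.csv` — one row per embryo transfer

| column | type | description |
| --- | --- | --- |
| `patient_id` | str | Must appear in `retrievals.csv`. |
| `retrieval_cycle_index` | int | The `cycle_index` of the source retrieval. |
| `transfer_index` | int | Consecutive from 1 within each patient, in treatment order (across cycles). |
| `transfer_day_label` | str | `day3` or `day5`; matches the source cycle's label. |
| `n_embryos_transferred` | int | Positive count. |
| `live_birth` | bool | Whether this transfer resulted in a live birth. |
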