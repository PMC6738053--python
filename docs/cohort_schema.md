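# Cohort CSV schema

One row per patient. Written by `hypoxvasc simulate-cohort` and consumed by
`hypoxvasc cohort` / `hypoxvasc analyze` and `hypoxvasc.pipeline`.

| column | type | values / units | notes |
| --- | --- | --- | --- |
| `patient_id` | str | | unique |
| `age` | float | years | |
| `grade` | str | `low`, `high` | |
| `histology` | str | `EEC`, `NEEC` | endometrioid vs non-endometrioid |
| `figo_stage` | str | `I-II`, `III-IV` | |
| `myometrial_invasion` | str | `<50%`, `>=50%` | |
| `lvsi` | str | `yes`, `no`, `missing` | `missing` recoded to `no` by `recode_lvsi` |
| `lymph_node_metastasis` | str | `yes`, `no`, `missing` | `missing` = no lymphadenectomy |
| `adjuvant` | str | `none`, `radiotherapy`, `chemotherapy` | |
| `caix_positive` | bool | | fCAIX > 1% |
| `mvd_high` | bool | | MVD above cohort median |
| `followup_months` | float | months | last follow-up / death |
| `recurrence` | str | `none`, `local`, `regional`, `distant` | |
| `recurrence_months` | float | months | NaN when no recurrence |
| `death` | str | `alive`, `other_cause`, `disease` | |
| `death_months` | float | months | NaN while alive |
| `event_time` | float | months | simulator's raw endpoint (min of event, censoring) |
| `event_observed` | int | 0/1 | simulator's raw event indicator |
| `true_linear_predictor` | float | log-hazard units | simulation truth for recovery tests |

Columns added by `hypoxvasc.cohort.derive_endpoints`:
`dss_time`, `dss_event`, `dfs_time`, `dfs_event`, `ddfs_time`, `ddfs_event`
(times in months, events 0/1).

Columns added by `hypoxvasc.cohort.add_groups`:
`biomarker_group` (`CAIX-`, `CAIX+/MVD-low`, `CAIX+/MVD-high`) and
`group_binary` (bool, double-positive vs rest).

Tables produced by `cohort_from_margins` contain only `group` plus the
categorical variables supplied in the margins map (no survival columns).
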