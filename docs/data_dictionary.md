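# Data dictionary

All tables are tab-separated text with a header row.  Period labels are
strings ("2010", "2015"); municipality and prefecture ids are strings
("M0042", "P03").

## Municipality panel (`panel.tsv`)

One row per municipality x sex x cause x period.

| column | meaning |
|---|---|
| `municipality_id` | municipality identifier |
| `prefecture_id` | prefecture the municipality belongs to |
| `sex` | `male` / `female` |
| `cause` | `all_causes`, `malignant_neoplasms`, `heart_disease`, `cerebrovascular_disease` |
| `period` | census year of the observation window |
| `o` | observed deaths pooled over the five-year window around the period |
| `pop_<age>` | person counts per five-year age group (`pop_00_04` ... `pop_85_plus`) |
| `population` | total population of the municipality in that period |
| `phn_total` | public health nurses, full-time-equivalent count |
| `phn_full_time` / `phn_part_time` | full-time and part-time PHN counts (part-time already converted to full-time equivalents) |
| `physicians` | physicians practicing in the municipality |
| `clinics` | medical clinics |
| `hospitals` | general hospitals in the secondary healthcare area |
| `welfare_facilities` | welfare facilities for the elderly requiring long-term care |

Optional `exclude_*` boolean columns mark rows removed by
`ebsmr.filter_panel` before analysis.

## Reference rates (`reference_rates.tsv`)

`age_group`, `sex`, `cause`, `rate` — base-year national mortality rates per
person-year, applied to both periods so SMRs stay longitudinally comparable.

## Adjacency (`adjacency.tsv`)

`municipality_a`, `municipality_b` — undirected edges of the municipality
adjacency graph used by the ICAR prior.

## EBSMR table (`ebsmr.tsv`)

One row per municipality x sex x cause x period: `o`, `e` (expected deaths),
`smr_raw` (100·o/e), `ebsmr` (100·posterior mean), `shrinkage_w`
(= e/(e+nu)), `prior_shape`, `prior_rate`, `degenerate` (complete shrinkage
flag).

## Truth record (`truth.json`)

Generator ground truth: `true_beta` (log-risk effects), `theta`
(municipality x period relative risks), `phi` (spatial field, sums to zero
per graph component), gamma prior parameters, secular `time_effect`, and the
baseline covariate means used for centering.

## Report bundle

`run_study` writes `descriptive.tsv`, `change.tsv`, `bivariate.tsv`,
`adjusted.tsv`, `stratified.tsv`, `bym.tsv`, `qvalues.tsv`, `ebsmr.tsv`,
`manifest.json` (config + hash + seed) and a human-readable `report.txt`.
Columns carry the fitted quantity, its standard error or credible interval,
the sample size, and a convergence flag where an iterative fit is involved.
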