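# Table schemas

All tables are plain CSV (RFC 4180, UTF-8, header row); XLSX with the same
columns is accepted by the readers. Angles are degrees, masses grams.
Absent values are empty fields. Floats are written at 6 significant digits.

## Extant measurement table (`read_extant_table` / `write_extant_table`)

| column       | type   | notes                                                  |
|--------------|--------|--------------------------------------------------------|
| taxon        | str    | binomial                                               |
| specimen_id  | str    |                                                        |
| pes          | enum   | `left` / `right` / `unknown` (aliases `l`, `r`, `?`)   |
| category     | enum   | `terrestrial` / `perching` / `predatory` / `scansorial`; aliases accepted: `ground-dwelling`, `grnd`, `climbing`, `clmb`, `raptorial`, `pred`, `prch` (case-insensitive) |
| body_mass_g  | float  | > 0; outside 36–1930 g warns but is kept               |
| IU, OU       | float  | ungual angles, [0, 360); at least one required         |
| IS, IS2, OS  | float  | sheath angles, optional                                |

One row per measured claw; left and right claws of a specimen are separate
rows. Rows failing validation are rejected and listed in the
`ValidationReport`, never silently dropped.

## Fossil table (`read_fossil_table` / `write_fossil_table`)

Same as above minus `category` and `body_mass_g`. `IU` and `OU` are
mandatory; `IS2` and `OS` must be jointly present or jointly absent
(sheath-bearing claws get Model 2 predictions).

## Landmark/outline file (`clawcurve measure`)

| column      | type  | notes                                   |
|-------------|-------|-----------------------------------------|
| claw_id     | str   | groups rows belonging to one claw       |
| metric      | enum  | IU / OU / IS / IS2 / OS                 |
| role        | enum  | `A`, `B`, or `outline`                  |
| point_index | int   | orders outline rows proximal → distal   |
| x, y        | float | unit-free coordinates                   |

Each (claw_id, metric) needs exactly one `A` row, one `B` row and ≥ 2
`outline` rows. Output: one row per claw with columns
`claw_id, IU, OU, IS, IS2, OS`, blanks for unmeasured metrics.

## Model file (`train` / `predict`)

Versioned JSON (`"format": "clawcurve-lda", "version": 1`) holding metrics,
categories, class means, pooled covariance, priors, scalings, proportion of
trace, grand mean and class counts.
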