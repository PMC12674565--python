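# Table schemas

All tables are CSV (canonical) or XLSX; column names are case-insensitive.
Coordinates are decimal degrees WGS84. Ratios must lie in (0.700, 0.760);
rows violating any invariant are rejected with a row-indexed diagnostic.

## `sm1` — bioavailable sample database (one measurement per row)

| column     | required | type  | notes                                        |
|------------|----------|-------|----------------------------------------------|
| site_id    | yes      | str   | sampling-site identifier                     |
| longitude  | yes      | float | −180…180                                     |
| latitude   | yes      | float | −90…90                                       |
| material   | yes      | str   | plant / soil / animal / human (synonyms like rodent → animal normalised) |
| sr_ratio   | yes      | float | ⁸⁷Sr/⁸⁶Sr                                    |
| sr_2sigma  | no       | float | 2σ measurement uncertainty, ≥ 0              |
| source     | no       | str   | originating study                            |

## `sm2` — archaeological/modern site table (rows grouped by site)

As `sm1` with `site` in place of `site_id`, plus:

| column           | required | type | notes                                       |
|------------------|----------|------|---------------------------------------------|
| period           | yes      | str  | e.g. LBA, Xiongnu, ME, modern ("modern" pools separately) |
| coord_provenance | no       | str  | exact / approximated-from-map / averaged    |
| summary_only     | no       | bool | row is a per-site summary, not an individual sample |

## `synthetic` — generator output

`sm1` plus an optional `true_ratio` column holding the generating cell's
true value, used by parameter-recovery tests.
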