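# Table formats

All tables are delimited text (comma or tab, autodetected), UTF-8, with a
header row; lines starting with `#` are comments.  Missing cells are
empty.  Column order is irrelevant; unknown columns are accepted with a
warning; missing required columns are an error.  Files written by the
package start with a provenance comment: tool version, run seed and
configuration hash.

## Amino-acid profiles (`aa_profile`)

| column | type | notes |
|---|---|---|
| sample_id | text | required |
| d15n_phe, d15n_glu, d15n_ala | ‰ vs air | required |
| station, habitat | text | optional; habitats RI/YPC/OPM/WPM/MOW/OSW/unknown |
| year | integer | optional |
| size_fraction | text | total, pico_0p2_3um, nano_micro_3_200um |
| sd_phe, sd_glu, sd_ala | ‰ | optional replicate SDs |
| n_replicates | integer | optional |

The trophic-call output appends `tp_glu`, `tp_ala`, `sd_tp_glu`,
`sd_tp_ala`, `mode`.

## End members (`endmember`)

`organism`, `group` (microalgae/bacteria/archaea/fungi/protozooplankton),
`n_source` (DIN/DON/prey), `d15n_phe`, `d15n_glu`, `d15n_ala`.

## Ratio matrices

Rows = classes, columns = pigments with the exact headers
`Chl b, But Fuco, Hex Fuco, Allo, Fuco, Perid, Zea, DV Chl b,
Chl c1+c2, Chl c3, Lut, Neo, Viola, Pras, Chl a`; the Chl a column must
be identically 1.  The packaged `initial_ratio_matrix()` /
`final_ratio_matrix()` reproduce the published matrices.

## Pigment samples

`sample_id` plus one column per pigment (µg L⁻¹), optional metadata
columns (station, year, habitat).

## CTD casts (`ctd`)

`depth` (m, strictly increasing), `temperature` (°C), `salinity`
(practical); optional `sigma_theta` (kg m⁻³), `oxygen` (mM),
`fluorescence`, `station`.

## Nutrient casts (`nutrients`)

`depth` (m), `nox` (NO₃+NO₂, µM); optional `po4`, `si`, `no2` (µM),
`bottom_depth` (m), `station`.

## Station features (`features`)

One row per station: any numeric predictor columns (NaN allowed) and a
required `label` column for tree training.
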