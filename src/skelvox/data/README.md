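# Embedded resources

All files are plain-text TSV/CSV and are loaded through `skelvox.db`.

## segments.tsv

One row per bone-segment record of one reference phantom. 340 rows: the
15-year-old and adult phantoms carry full male and female tables whose
printed-identical rows are de-duplicated downstream when counting unique
segments.

| column        | meaning                                                        |
|---------------|----------------------------------------------------------------|
| table_id      | source table within the database (t7..t14)                     |
| age_group     | newborn, 1y, 5y, 10y, 15y, adult                               |
| sex           | any (children), male, female                                   |
| site          | skeletal site with active hematopoiesis                        |
| segment       | segment name within the site                                   |
| shape         | b box, c cylinder, dc deformed cylinder, p triangular prism, e ellipsoid, t tube |
| h,a,b,c,d     | linear dimensions, mm (c,d only for deformed cylinders)        |
| cortical      | cortex spec as `face:thickness_mm` pairs joined by `+`; empty means no cortex |
| bvtv          | bone volume fraction of spongiosa (0-1)                        |
| tb_th         | mean trabecular thickness, mm                                  |
| sigma_tb_th   | intra-specimen CV of trabecular thickness, %                   |
| tb_sp         | mean trabecular separation, mm                                 |
| sigma_tb_sp   | intra-specimen CV of trabecular separation, %                  |

Transcription notes: the printed compound cortex strings (e.g. a tube with
`0.5` on the lateral surface and `3.6` on one base) are tokenized here into
explicit `face:thickness` pairs; `h` printed as a covered face of a curved
shape denotes its lateral surface and is stored as `lateral`. Duplicate
printed names (the 1-year sacrum prints five rows named "Body") are
disambiguated with ordinal suffixes. Unicode dashes are stored as ASCII `-`.
Everything else is as printed, including evident typos: those are repaired
only by `curations.csv` in curated mode.

## curations.csv

One row per field-level deviation applied in curated mode, keyed by
(age_group, sex, site, segment, field), with the printed value, the curated
value and a justification. `field = sex_distinct` marks a printed-identical
male/female row pair that the shape census requires to be counted as two
unique segments. An empty curated value clears the field.

## am_distribution.tsv

Active-marrow fractions (% of whole-body AM) per skeletal site and phantom.
`sites` holds one site or a `;`-joined group sharing a single printed value
(the adult clavicle+scapula+ribs cell). Sites without AM at an age are absent.

## composition.tsv

Element mass fractions (%) of the two simulated media.

## densities.tsv

Media densities (g/cm^3) per age group.

## multiplicity.tsv

Default n_s (how many copies of the segment the skeleton contains) and k_s
(whole-structure volume over modeled-fragment volume for truncated segments).
These are package defaults reconstructed from gross anatomy - the published
source ships the exact values only as supplementary material - and every
value is overridable at run time.
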