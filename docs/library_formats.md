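# Spectral-library and transition-database formats

## Raw library dialects (input to `parse_spectra` / `build-library`)

All three dialects carry the same record: one acquired MS/MS spectrum,
keyed by its SPLASH (a database-independent spectral hash, treated here as
an opaque grouping identifier), with the compound's neutral monoisotopic
mass and a fragment peak list.

### MSP (NIST-style blocks)

One blank-line-separated block per spectrum:

```
NAME: L-Tryptophan
SPLASH: splash10-0002-0900000000-aaaa
COMPOUND_ID: HMDB0000929
EXACTMASS: 204.08988
IONMODE: positive
RESOLUTION: high
COLLISION_ENERGY: 35
Num Peaks: 3
146.0600 999
188.0706 450
118.0651 30
```

Required: `NAME`, `SPLASH`, `EXACTMASS` (Da), `IONMODE`
(positive/negative), `Num Peaks` and the peak list. Optional:
`COMPOUND_ID`, `RESOLUTION` (high/low, default high), `COLLISION_ENERGY`
(eV; anything unparseable is stored as unknown).

### CSV (one row per fragment)

Columns: `compound_id, splash_id, compound_name, neutral_mass, polarity,
resolution, collision_energy, fragment_mz, fragment_intensity`.
Rows sharing a `splash_id` form one spectrum; spectrum-level fields are
taken from the first row of each group.

### JSON (one object per spectrum)

```json
[{"splash_id": "...", "compound_id": "...", "compound_name": "...",
  "neutral_mass": 204.08988, "polarity": "positive",
  "resolution": "high", "collision_energy": 35,
  "fragments": [[146.06, 999.0], [188.0706, 450.0]]}]
```

### HMDB exports

Bulk HMDB parsing is out of scope. `speclib.HMDB_FIELD_MAPPING` documents
the field correspondence a converter must honour to produce the CSV
dialect above.

## DIA transition database (output of curation)

CSV, one row per (precursor adduct x curated fragment):

| column | meaning |
| --- | --- |
| `compound_id`, `splash_id`, `compound_name` | record identity |
| `neutral_mass` | Da |
| `polarity` | positive / negative |
| `adduct` | e.g. `[M+H]+` |
| `precursor_mz` | adduct m/z, Da |
| `window_index` | SWATH isolation-window index (0-based) |
| `fragment_mz` | Da |
| `relative_intensity` | % of base peak, (5, 100] |
| `tag` | `D` (main daughter, > 75%) or `F` (secondary) |

An equivalent nested JSON form (`--out db.json`) groups precursors and
fragments under one object per compound.

## Adduct table

`swath_annotator/adducts.csv` (editable; `name, polarity, mass_delta,
mode`).  Mass deltas are sums of atomic masses of the transferred atoms
minus charge x electron mass.  The `mode` column resolves the anomalous
`[M-Cl]-` species: `default` rows implement chloride attachment, the
`strict` row literal chlorine loss; `load_adduct_table(chloride=...)`
selects between them.
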