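# Supplementary charge dataset (not distributed)

The full-dataset statistics (21-method covariance/correlation PCA, the
Hirshfeld-I regression, PC-fit table, GCD subset selection) are computed
from the published supporting-information spreadsheet of per-atom charges
for the pooled GMTKN55 molecule set.  That workbook is not redistributed
with this package.

To run the full-dataset reproduction (`tests/test_acceptance.py::
test_supplementary_dataset_reproduction`), place here:

- `charges.xlsx` — the SI workbook: identifier columns
  (`molecule_id`, `atom_index`, `element`) plus one column per charge
  method; empty cells are holes and are handled by complete-case
  filtering.
- `mapping.json` — a JSON object mapping each spreadsheet charge column
  name to the canonical method names used by the tests:
  `VDD, Hirshfeld, CHELPG, MK, RESP, HLY, ISA, DDEC6, MBIS, Hirshfeld-I,
  MBSBickelhaupt, NPA, IBO, MBSMulliken, i-ACP, ACP, CM5, EEQ, QTAIM,
  APT, ADCH`.

Example `mapping.json`:

```json
{"Hirshfeld-I charges": "Hirshfeld-I", "QTAIM (Bader)": "QTAIM"}
```

Without these files the full-dataset test fails with a FileNotFoundError;
all synthetic-data tests are unaffected.
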