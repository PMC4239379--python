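# External data (user-supplied)

Two acceptance tests consume the study's deposited data, which cannot be
redistributed here. To run them, place:

- `osxylp_proteins.fasta` — the 21 family protein sequences from the
  Dryad archive (doi:10.5061/dryad.44tj3), with record ids matching the
  gene names of the packaged family table (`OsLTPL1`, `OsXYLP2`, ...).
- `table_s2_est_counts.tsv` — the supplementary EST count table exported
  as TSV: gene names in the first column, tissue columns of integer
  counts.

Without these files the corresponding tests in
`tests/test_acceptance.py::TestDepositedData` fail with instructions.
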