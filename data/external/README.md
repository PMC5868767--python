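# External inputs for published-value reproduction

The three reproduction tests in `tests/test_acceptance.py` need inputs
that must be fetched from public databases; they are not distributed with
the package. Place the following files here:

- `reference_pair.faa` — protein FASTA with exactly two records: the
  CSC-L1 family homolog (NCBI accession XP_001010624) followed by the CSC
  family homolog (XP_014661822).
- `superfamily_s1.faa` — the 69-sequence superfamily FASTA (supplementary
  sequence file of the source study), with TCDB-style identifiers
  (`1.A.17.<family>.<system>`) as the first header token.
- `reference_structure.pdb` — coordinates of the fungal channel structure
  (PDB entry 4WIS or 4WIT, one chain).
- `reference_tms.tsv` — tab-separated table with columns `start` and
  `end`: the 1-based inclusive residue ranges of that chain's ten
  membrane-spanning helices, in sequence order.

Without these files the three tests fail with a message naming what is
missing; all other tests are self-contained.
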