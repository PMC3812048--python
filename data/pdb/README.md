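# Crystal-structure inputs

The crystal-structure worked examples (gate distances for the three
transporter conformations) need PDB-format coordinate files here:

    data/pdb/2JLO.pdb   outward-facing occluded (ion + substrate bound)
    data/pdb/2X79.pdb   inward-facing apo
    data/pdb/2JLN.pdb   outward-facing ion-bound

Each is a one-time ~1 MB download:

    for id in 2JLO 2X79 2JLN; do
        curl -o data/pdb/$id.pdb https://files.rcsb.org/download/$id.pdb
    done

`scripts/acceptance.py` attempts the download automatically when a file is
missing and network access is available; otherwise the corresponding
targets are omitted from the report. The related tests in
`tests/test_acceptance.py` fail with an actionable message until the files
are provided (everything else in the test suite is self-contained).
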