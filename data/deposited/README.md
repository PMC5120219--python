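# Deposited coordinates

The crystallographic checks in `tests/test_acceptance.py` read real PDB
entries from this directory (lower-case names):

- `4xhz.pdb` — human PCDH15 EC8-10
- `5kj4.pdb`  — mouse Pcdh15 EC9-10 (four protomers)
- `3ubg.pdb`  — Drosophila N-cadherin EC1-4 (calcium-free EC2-3 linker)
- `1l3w.pdb`  — C-cadherin ectodomain (EC4-5 linker comparison)

The files are not redistributed with the package; download them from the
PDB (e.g. `https://files.rcsb.org/download/4XHZ.pdb`) into this directory
to enable those tests. Everything else in the test suite runs on
synthetic data and needs no download.
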