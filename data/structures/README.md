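# Deposited structures (optional)

Accession-gated tests and acceptance targets t2–t7 need the deposited
family structures. This build environment has no network access, so they
are not bundled. To enable them, download the entries below from the PDB
and save them here as lower-case `<accession>.pdb` (or `.cif`):

2CPL (PPIA reference), 2R99, 2ESL, 2GW2, 2BIT, 2HQ6, 1QOI, 1XWN (NMR;
model 1 is used), 1ZKC, 1CYN, 2A2N, 2HE9, 2OK3, plus 1AK4 for the PPIA
docking screen.

When absent, the gated tests skip with a message and
`scripts/acceptance.py` omits the corresponding target ids.
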