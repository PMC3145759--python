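# data/

The Notch1 NRR crystal structure is not redistributed with this package.
To enable the reproduction-tier acceptance tests and
`analysis/05_nrr_reproduction.py`, download PDB entry 3ETO

    https://www.rcsb.org/structure/3ETO  (PDB format)

and save it here as `3ETO.pdb`.
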