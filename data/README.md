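Place the cryo-EM coordinate files 3J5P.pdb (apo) and 3J5R.pdb
(capsaicin-bound), downloaded from https://files.rcsb.org/download/,
in this directory to enable the structural-ruler test
(tests/test_acceptance.py) and `capsgate struct --ruler` on the real
structures. They are not redistributed with the package.
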