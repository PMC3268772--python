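Microsatellite statistics — whole lab
Per-marker genotype counts and allele size ranges over the entire database.
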