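DNA and storage locations — project {project}
One row per DNA extraction with its source samples and storage path.
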