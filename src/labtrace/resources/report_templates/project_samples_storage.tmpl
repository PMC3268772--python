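Samples and storage locations — project {project}
One row per sample with its full storage path.
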