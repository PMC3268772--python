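Sequence statistics — project {project}
Per-marker counts and length statistics within one project.
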