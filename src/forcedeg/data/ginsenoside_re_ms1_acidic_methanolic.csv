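mz
783.4897
829.4921
797.5040
843.5076
765.4802
811.4828
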