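mz
783.4897
829.4921
765.4802
811.4828
801.5026
847.5050
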