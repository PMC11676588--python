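mz
979.5447
1025.5494
995.5386
1041.5441
961.5375
1007.5393
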