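"""Reference sequences used as default fixtures."""

# Human amyloid-beta 1-42; serines at positions 8 and 26, K28-A42 salt
# bridge partners at the C-terminus.
AB42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

assert len(AB42) == 42
assert AB42[7] == "S" and AB42[25] == "S"
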