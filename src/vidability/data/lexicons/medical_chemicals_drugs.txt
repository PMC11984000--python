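# lexicon: medical
# category: chemicals_drugs
insulin
metformin
lantus
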