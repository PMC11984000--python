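# lexicon: summary
finally
in a word
in brief
briefly
in conclusion
in the end
in the final analysis
on the whole
thus
to conclude
to summarize
in sum
to sum up
in summary
lastly
in short
by and large
consequently
as a result
hence
overall
after all
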