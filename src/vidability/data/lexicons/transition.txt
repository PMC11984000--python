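# lexicon: transition
accordingly
as a result
and so
because
consequently
for that reason
hence
on account of
since
therefore
thus
after
afterwards
always
at length
during
earlier
following
immediately
in the meantime
later
never
next
once
simultaneously
so far
sometimes
soon
subsequently
then
this time
until now
when
whenever
while
additionally
again
also
and
or
not
besides
even more
finally
first
firstly
further
furthermore
in addition
in the first place
in the second place
last
lastly
moreover
second
secondly
after all
although
and yet
at the same time
but
despite
however
in contrast
nevertheless
notwithstanding
on the contrary
on the other hand
otherwise
thought
yet
as an illustration
eg
for example
for instance
specifically
to demonstrate
to illustrate
briefly
critically
foundationally
more importantly
of less importance
primarily
above
centrally
opposite to
adjacent to
below
peripherally
nearby
beyond
in similar fashion
in the same way
likewise
in like manner
ie
in other word
that is
to clarify
to explain
in fact
of course
undoubtedly
without doubt
surely
indeed
for this purpose
so that
to this end
in order that
to that end
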