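# Determiners
a
an
the
this
that
these
those
# Prepositions
aboard
about
above
across
after
against
along
amid
among
around
as
at
before
behind
below
beneath
beside
besides
between
beyond
but
by
concerning
considering
despite
down
during
except
excluding
following
for
from
in
inside
into
like
minus
near
of
off
on
onto
opposite
outside
over
past
per
plus
regarding
since
through
throughout
to
toward
towards
under
underneath
unlike
until
up
upon
versus
via
with
within
without
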