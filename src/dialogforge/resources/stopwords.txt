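# Packaged English stopword inventory (one per line, '#' starts a comment).
# Function words only; domain prepositions that carry slot structure at the
# surface level (with/at/for/to/...) are included, since slot information is
# recovered from entity spans, not from prepositions.
a
an
the
this
that
these
those
i
you
he
she
it
we
they
me
him
her
us
them
my
your
his
its
our
their
am
is
are
was
were
be
been
being
do
does
did
have
has
had
will
would
shall
should
can
could
may
might
must
and
or
but
if
then
else
of
in
on
at
by
for
with
to
from
into
about
as
not
no
so
too
very
please
what
when
where
who
whom
which
whose
why
how
since
until
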