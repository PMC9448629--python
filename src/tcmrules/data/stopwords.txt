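a
an
the
this
that
these
those
he
she
it
he/she/it
they
them
him
her
his
hers
its
their
theirs
i
me
my
we
us
our
you
your
and
or
but
nor
so
yet
for
of
in
on
at
by
to
from
with
as
is
are
was
were
be
been
being
am
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
not
no
if
then
than
too
very
such
only
also
just
about
into
over
under
again
there
here
when
where
who
whom
which
what
while
because
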