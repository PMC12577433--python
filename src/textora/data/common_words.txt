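# Synthetic stand-in for a top-frequency word list (generic English plus
# high-frequency biomedical reporting vocabulary), used as the reference
# centroid for embedding-based stopword derivation.
the
of
and
a
in
to
is
was
for
that
with
as
on
by
be
this
are
at
or
from
an
were
which
have
has
not
but
also
can
may
been
its
it
their
these
during
between
both
more
other
into
such
than
several
various
within
through
each
some
most
all
many
one
two
three
first
second
using
used
use
based
via
following
among
along
upon
after
before
under
over
about
however
therefore
thus
although
while
when
where
whether
because
since
due
result
results
resulting
studies
study
shown
show
shows
showed
found
find
findings
known
known
well
highly
important
role
roles
involved
involvement
associated
association
related
relation
required
similar
specific
specifically
including
include
includes
observed
observe
reported
report
suggest
suggests
suggested
indicate
indicates
indicated
demonstrate
demonstrates
demonstrated
described
describe
identified
identify
characterized
characterize
exhibits
exhibit
exhibited
contains
contain
containing
present
presence
absent
absence
possible
likely
unlikely
common
commonly
widely
generally
primarily
mainly
largely
approximately
respectively
additionally
furthermore
moreover
finally
recently
previously
currently
often
frequently
rarely
usually
typically
mostly
nearly
either
neither
against
across
toward
towards
without
whereas
may
might
could
would
should
must
able
unable
new
novel
recent
early
late
large
small
high
low
higher
lower
increased
increase
increases
increasing
decreased
decrease
decreases
decreasing
reduced
reduce
reduction
enhanced
enhance
enhancement
affected
affect
affects
effect
effects
caused
cause
causes
causing
leads
lead
leading
plays
play
played
acts
act
acting
appears
appear
appeared
remains
remain
remained
occurs
occur
occurred
become
becomes
became
given
taken
made
make
makes
provide
provides
provided
obtained
obtain
number
numbers
level
levels
type
types
form
forms
part
parts
group
groups
member
members
family
families
term
terms
example
examples
case
cases
data
analysis
analyses
method
methods
approach
approaches
model
models
system
systems
process
processes
function
functions
functional
structure
structures
structural
activity
activities
active
region
regions
site
sites
domain
domains
factor
factors
pathway
pathways
mechanism
mechanisms
response
responses
expression
expressed
express
encoded
encodes
encode
encoding
gene
genes
protein
proteins
cell
cells
cellular
human
patients
patient
tissue
tissues
molecular
biological
clinical
normal
different
differences
difference
important
significant
significantly
major
minor
main
key
central
essential
critical
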