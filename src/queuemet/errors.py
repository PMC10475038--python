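"""Exception hierarchy.

Every named failure mode of the public API raises a distinct subclass of
:class:`QueuemetError` so callers (and the CLI) can report precise reasons.
"""


class QueuemetError(Exception):
    """Base class for all queuemet errors."""


# -- network definition / file format ---------------------------------------

class MalformedSection(QueuemetError):
    """A network file section is structurally invalid or carries unknown keys."""


class MissingPoolReference(QueuemetError):
    """A reaction or flow names a pool that does not exist in the network."""


class DuplicateId(QueuemetError):
    """Two pools, reactions or flows share an id."""


class NonPositiveConstant(QueuemetError):
    """A kinetic constant or packet size violates its positivity constraint."""


class UnwritableLocation(QueuemetError):
    """The target path for a network file cannot be written."""


class UnknownPool(QueuemetError):
    """An operation referenced a pool id absent from the network."""


class SelfLump(QueuemetError):
    """Attempt to lump a pool with itself."""


# -- kinetics ----------------------------------------------------------------

class MissingConcentration(QueuemetError):
    """A rate evaluation lacked a concentration for a referenced pool."""


class NegativeConcentration(QueuemetError):
    """A concentration passed to a rate law was negative."""


class ReverseAlreadySet(QueuemetError):
    """apply_reverse_default called on a law that already has a reverse velocity."""


# -- engine ------------------------------------------------------------------

class TimestepConditionViolated(QueuemetError):
    """The mu << 1 time-step condition failed at the initial state."""


class DegenerateSeries(QueuemetError):
    """A dispersion statistic was requested for a trace with zero mean."""


# -- literature statistics ---------------------------------------------------

class TooFewValues(QueuemetError):
    """A Gaussian fit needs at least two measurement records."""


# -- GA tuner ----------------------------------------------------------------

class ZeroReferenceEntry(QueuemetError):
    """The literature loss is undefined when a reference concentration is zero."""


class SeriesTooShort(QueuemetError):
    """The stability loss tail is longer than the recorded series."""


# -- sensitivity -------------------------------------------------------------

class DegenerateVariance(QueuemetError):
    """Pooled endpoint variance is zero; the variance ratio is defined as 0."""


class EmptyScores(QueuemetError):
    """Quantile aggregation of an empty score collection."""


# -- fixtures ----------------------------------------------------------------

class SizeTooSmall(QueuemetError):
    """A fixture network was requested with fewer than two pools."""
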