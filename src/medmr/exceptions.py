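"""Exception hierarchy for the medmr pipeline.

Estimators raise on inputs that cannot support them; the screening layer
catches :class:`EmptyInstrumentSetError` and records the pair as skipped
instead of aborting a whole screen.
"""


class MedMRError(Exception):
    """Base class for all medmr errors."""


class SumstatsFormatError(MedMRError):
    """A summary-statistics file is malformed (e.g. a mandatory column is missing)."""


class EmptyInputError(MedMRError):
    """An input file or record collection is empty."""


class EmptyInstrumentSetError(MedMRError):
    """No instruments survive selection/harmonization/filtering for a pair."""


class InsufficientInstrumentsError(MedMRError):
    """Fewer instruments than the method's minimum (e.g. Egger needs k >= 3)."""


class DegenerateInstrumentError(MedMRError):
    """An instrument has zero exposure effect, so its Wald ratio is undefined."""
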