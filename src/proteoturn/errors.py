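"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: :class:`SchemaError` -> 2,
:class:`StatsPreconditionError` -> 3, anything else -> 1.
"""


class ProteoturnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ProteoturnError, ValueError):
    """An input table violates the documented column/row contract."""


class StatsPreconditionError(ProteoturnError, ValueError):
    """A statistical routine was called on data that cannot support it."""


class LabelingDomainError(ProteoturnError, ValueError):
    """A peptide measurement falls outside the labeling model's log domain.

    Records raising this are *flagged* invalid (with :attr:`reason`) by the
    table-level pipeline rather than aborting the run.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
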