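"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors are raised by click itself
(exit 2), :class:`DataFormatError` maps to exit 3, :class:`ConvergenceError`
to exit 4.
"""


class MdcapError(Exception):
    """Base class for all package errors."""


class DataFormatError(MdcapError):
    """An input file or table does not match the expected dialect."""


class EmptyNetworkError(DataFormatError):
    """No records survive filtering, so no bipartite network can be built."""


class AlignmentError(MdcapError):
    """Matrices that must share labels and order do not."""


class NoOntologyError(MdcapError):
    """A disease name cannot be resolved to any MeSH tree number."""


class ConvergenceError(MdcapError):
    """Label propagation did not converge within the iteration cap."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
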