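"""Exception hierarchy for bindscape.

Every error raised by the library derives from :class:`BindscapeError`, so
callers can catch one type at pipeline level while tests can assert on the
specific failure mode.
"""


class BindscapeError(Exception):
    """Base class for all bindscape errors."""


class ParseError(BindscapeError):
    """Input text could not be parsed (e.g. PDB with no CA atoms)."""


class StructureError(BindscapeError):
    """Structure violates a contract (chain count, homodimer symmetry...)."""


class TopologyError(BindscapeError):
    """Topology cannot be built (e.g. chain shorter than 2 beads)."""


class IntegrationError(BindscapeError):
    """Dynamics diverged; message names the time step."""


class ConvergenceError(BindscapeError):
    """Self-consistent iteration exceeded max_iter; carries the residual."""


class ConnectivityError(BindscapeError):
    """Histograms from neighbouring temperatures do not overlap."""


class PartitionError(BindscapeError):
    """Native/non-native partition is degenerate (one side empty)."""


class NoPeakError(BindscapeError):
    """A thermal curve has no interior maximum."""


class MeasureError(BindscapeError):
    """A topography measure is undefined for the given moments."""


class EstimationError(BindscapeError):
    """A statistical estimate cannot be formed (e.g. all trajectories censored)."""


class ConstructionError(BindscapeError):
    """Synthetic-data generator cannot satisfy the requested spec."""


class ConfigError(BindscapeError):
    """Pipeline configuration invalid or incomplete."""


class FormatError(BindscapeError):
    """An artifact file violates its schema; message carries the line number."""
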