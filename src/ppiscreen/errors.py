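"""Exception hierarchy shared across the package."""


class PpiScreenError(Exception):
    """Base class for all package-specific errors."""


class EmptyGeneListError(PpiScreenError):
    """Gene-list file contained no symbols after comment/blank filtering."""


class EdgeTableParseError(PpiScreenError):
    """Malformed edge-table row; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class ConfigurationError(PpiScreenError):
    """Invalid parameter value (unknown metric, out-of-range threshold, bad spec)."""


class DegenerateNetworkError(PpiScreenError):
    """The requested analysis scope contains no usable component."""


class GraphTooLargeError(PpiScreenError):
    """Brute-force oracle invoked on a graph above its node-count guard rail."""


class NetworkTooSmallError(PpiScreenError):
    """Degree-tail summary requested on a network with too few non-isolated nodes."""
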