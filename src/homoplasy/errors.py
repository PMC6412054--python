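"""Exception hierarchy shared across the package."""


class HomoplasyError(Exception):
    """Base class for all errors raised by this package."""


class InputError(HomoplasyError):
    """Invalid user-supplied input (empty file, duplicate labels, bad character...)."""


class NewickParseError(InputError):
    """Malformed Newick; carries the approximate line/column of the offence."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class AlignmentError(InputError):
    """Alignment invariant violated (unequal sequence lengths, no records...)."""


class LabelMismatchError(InputError):
    """Tree tips and alignment labels are not in 1:1 correspondence."""


class SimulationError(HomoplasyError):
    """Simulation could not complete (epidemic repeatedly died out, eligibility exhausted...)."""
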