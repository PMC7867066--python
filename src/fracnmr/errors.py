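"""Exception hierarchy.

Input/format problems raise :class:`InputError` subclasses (CLI exit code 2);
numerical failures raise :class:`NumericalError` subclasses (exit code 3).
"""


class FracNMRError(Exception):
    """Base class for all package errors."""


class InputError(FracNMRError):
    """Invalid or unparsable input."""


class NumericalError(FracNMRError):
    """A computation failed or is undefined for the given values."""


class UnknownResidueError(InputError):
    def __init__(self, residue: str):
        self.residue = residue
        super().__init__(f"unknown residue type: {residue!r}")


class UnknownBondError(InputError):
    def __init__(self, residue: str, bond, valid):
        self.residue = residue
        self.bond = tuple(bond)
        self.valid = sorted(tuple(b) for b in valid)
        super().__init__(
            f"{residue}: no carbon-carbon bond {tuple(bond)}; valid bonds: {self.valid}"
        )


class ExcludedResidueError(InputError):
    """Residue type excluded by construction (e.g. Gly/Pro in CB/CA analysis)."""


class UndefinedProbabilityError(NumericalError):
    """Conditional probability with zero-probability conditioning event."""


class FitError(NumericalError):
    """Curve fitting failed or produced an unphysical parameter."""


class ParseError(InputError):
    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
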