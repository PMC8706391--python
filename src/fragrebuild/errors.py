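"""Exception types shared across the pipeline."""


class FragrebuildError(Exception):
    """Base class for all package errors."""


class SmilesParseError(FragrebuildError, ValueError):
    """A SMILES string could not be parsed into a valid structure."""

    def __init__(self, smiles: str, reason: str = "unparseable or valence-violating SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class ContractError(FragrebuildError, ValueError):
    """A precondition of an operation was violated by the caller."""


class CouplingInfeasibleError(FragrebuildError):
    """No chemically valid bond can be formed between header and body."""


class InfeasibleSolutionError(FragrebuildError):
    """A search solution cannot be realized into a valid molecule."""


class InfeasibleStartError(FragrebuildError):
    """No feasible initial solution could be sampled for the search."""
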