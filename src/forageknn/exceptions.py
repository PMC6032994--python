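"""Exception hierarchy shared across the package."""


class ForageKnnError(Exception):
    """Base class for all package-specific errors."""


class ContractError(ForageKnnError, ValueError):
    """An input violated a documented precondition."""


class BudgetError(ForageKnnError, ValueError):
    """A deterministic search was requested beyond its evaluation budget."""


class FormatError(ForageKnnError, ValueError):
    """A data file does not conform to the expected CSV dialect."""


class StratificationError(ForageKnnError, ValueError):
    """Stratified folds cannot be built (a class is too small or absent)."""


class UndefinedMetricError(ForageKnnError, ValueError):
    """A performance metric is undefined for the given counts/scores."""
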