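"""Exception hierarchy for the PDT toolkit.

Error categories mirror the failure modes of the pipeline stages: malformed
input files, invalid data content, bad parameters, broken caller contracts,
untrainable datasets, and invalid run configuration.
"""


class PDTError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PDTError):
    """Input file does not match the expected layout (missing columns, bad header)."""


class DataError(PDTError):
    """Input data is structurally valid but unusable (non-monotonic time, too short, empty)."""


class ParameterError(PDTError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class ContractError(PDTError, ValueError):
    """A caller violated an API precondition (wrong dimensionality, empty input, non-unit vector)."""


class TrainingError(PDTError):
    """A classifier cannot be trained on the given dataset (e.g. a single class present)."""


class ConfigError(PDTError):
    """Run configuration failed schema validation."""
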