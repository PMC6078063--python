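"""Package-specific exception types."""


class DataError(ValueError):
    """Invalid or inconsistent input data."""


class EmptyDatasetError(DataError):
    """No sequences survived reading/filtering."""


class ModelVersionError(RuntimeError):
    """Model file incompatible with the current k-mer catalog ordering."""


class TrainingError(RuntimeError):
    """Training diverged or could not proceed."""
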