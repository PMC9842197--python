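"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter registry, preset or design is malformed."""


class InputError(ValueError):
    """A user-supplied file or argument is invalid."""


class AccountingError(ValueError):
    """A profit statement violates its balance identity."""


class SequencingError(RuntimeError):
    """An operation was called before its prerequisite submodels ran."""
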