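"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid user input: bad file contents, parameters out of range,
    or data that violates a pipeline precondition (e.g. a missing control
    amplicon). CLI entry points translate this into exit code 2."""
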