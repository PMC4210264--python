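"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Raised when an input (file, image, parameter) violates a precondition."""


class AnalysisError(RuntimeError):
    """Raised when an analysis step cannot produce a meaningful result.

    Examples: no fingerprint foreground found, no ridge structure in the
    analysis region, no SVM configuration meeting the accuracy standard.
    """
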