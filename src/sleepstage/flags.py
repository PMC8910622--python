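"""Warning category for degenerate-input feature conventions."""

import warnings


class DegenerateEpochWarning(UserWarning):
    """An epoch hit a degenerate case (zero variance, empty band, no template
    matches); the affected feature was set to its documented fallback value."""


def flag(message: str) -> None:
    warnings.warn(message, DegenerateEpochWarning, stacklevel=3)
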