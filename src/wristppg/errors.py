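"""Exception hierarchy for the wristppg pipeline.

Stage failures carry enough context (subject, frame, wavelength) for the
orchestrator to report which pipeline stage rejected which input.
"""


class WristPPGError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(WristPPGError):
    """A configuration value is infeasible (bad cutoff, ratio outside (0, 1), ...)."""


class NoPulsationError(WristPPGError):
    """A frame carries no detectable cardiac pulsation (flat or sub-prominence)."""


class InvalidBaselineError(WristPPGError):
    """The DC estimate is non-positive, so the AC/DC ratio is undefined."""


class UnreliableSubjectError(WristPPGError):
    """Peak/valley detection failed on too many of a subject's frames."""


class DegenerateFrameError(WristPPGError):
    """A frame is constant or otherwise degenerate for feature computation."""
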