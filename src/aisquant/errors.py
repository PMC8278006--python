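"""Exception hierarchy.

Every failure mode that callers are expected to handle programmatically has
its own class; all inherit from :class:`AISQuantError` so pipeline code can
catch the whole family.
"""


class AISQuantError(Exception):
    """Base class for all aisquant errors."""


class ConfigError(AISQuantError):
    """Invalid run configuration (bad value, unknown key, missing path)."""


class ProfileError(AISQuantError):
    """Invalid intensity profile or profile operation."""


class NoAISDetectedError(ProfileError):
    """Boundary detection found no positive signal (peak <= 0)."""


class FeatureError(AISQuantError):
    """Feature extraction failed (profile too short, degenerate moments...)."""


class EphysError(AISQuantError):
    """Electrophysiology feature extraction failed or is undefined."""


class PipelineError(AISQuantError):
    """A pipeline stage failed; the message names the first failing record."""
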