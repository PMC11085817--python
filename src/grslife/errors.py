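"""Exception hierarchy.

All grslife errors derive from :class:`GRSLifeError` so callers can catch the
package's failures with a single except clause while letting programming
errors propagate.
"""


class GRSLifeError(Exception):
    """Base class for all grslife errors."""


class ConfigError(GRSLifeError):
    """Invalid simulation or pipeline configuration."""


class InputError(GRSLifeError):
    """Malformed or inconsistent input data (files, tables, alleles)."""


class FitError(GRSLifeError):
    """A statistical model failed to fit (non-convergence, separation,
    degenerate design)."""
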