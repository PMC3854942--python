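"""Exception hierarchy shared across the pipeline.

Every error carries an ``exit_code`` so the command-line layer can map
failure classes to distinct process exit statuses (configuration errors
exit 2, data/schema errors exit 3, numerical failures exit 4).
"""


class MagfluxError(Exception):
    """Base class for all magflux errors."""

    exit_code = 1


class ConfigError(MagfluxError):
    """Invalid configuration: unknown keys, bad presets, probe mismatches."""

    exit_code = 2


class ScheduleError(ConfigError):
    """Malformed protocol schedule (overlap, gap, bad segment)."""


class DataError(MagfluxError):
    """Invalid or inconsistent data (schema violations, missing samples)."""

    exit_code = 3


class CalibrationError(DataError):
    """Failed in-situ calibration (e.g. Rmax <= Rmin, missing plateau)."""


class NumericError(MagfluxError):
    """Numerical failure (negative concentrations, non-convergence)."""

    exit_code = 4
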