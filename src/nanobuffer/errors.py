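"""Exception taxonomy shared by the library and the CLI.

Each class carries an ``exit_code`` so the command-line layer can map
failures onto a stable, documented code set:

    1  usage errors (bad flags, missing files)
    2  configuration / table-schema errors
    3  numerical or solver failures
    4  data-quality problems (degenerate inputs, undefined ratios)
"""


class NanobufferError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(NanobufferError, ValueError):
    """A caller-supplied value violates a precondition."""

    exit_code = 1


class ConfigError(NanobufferError):
    """Malformed run configuration (unknown key, missing path...)."""

    exit_code = 2


class SchemaError(ConfigError):
    """A table is missing a required column or holds non-numeric cells."""

    exit_code = 2


class SolverError(NanobufferError):
    """A root-finder or integrator failed to converge."""

    exit_code = 3


class StepSizeError(SolverError):
    """A simulation step moved the state further than the method allows."""

    exit_code = 3


class DataQualityError(NanobufferError):
    """Input data are formally valid but unusable (flat curve, empty mask...)."""

    exit_code = 4


class DegenerateStepError(DataQualityError):
    """Repeated pH readings span a titrant increment; derivative undefined."""


class EstimationError(DataQualityError):
    """An estimator cannot produce a value from these data."""


class UndefinedRatioError(DataQualityError):
    """Background-corrected denominator is non-positive for a punta."""


class ExtrapolationError(DataQualityError):
    """A ratio lies outside the calibrated range."""
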