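"""Exception hierarchy.

Every stage of the costing pipeline raises a distinct subclass of
:class:`KhscmError` so the CLI can map a failure to the stage that caused it.
"""


class KhscmError(Exception):
    """Base class for all package errors."""


class LedgerError(KhscmError):
    """A fixture file is malformed or internally inconsistent."""


class ParameterError(KhscmError):
    """An operation received an out-of-domain parameter (zero lifetime, nonpositive rate...)."""


class ConfigError(KhscmError):
    """An allocation / scenario / generator configuration is invalid."""


class AllocationError(KhscmError):
    """Step-down allocation cannot proceed (e.g. all-zero basis weights)."""


class UnitCostError(KhscmError):
    """Unit costs undefined: nonzero cost against a zero output count."""


class CostingError(KhscmError):
    """Episode costing failed (unpriced item, missing inpatient unit costs...)."""


class ImputationError(KhscmError):
    """In-kind or salary imputation failed (unpriced code, unknown cadre)."""


class AggregationError(KhscmError):
    """National aggregation failed (stratum without a sampling weight)."""


class ScenarioError(KhscmError):
    """Scenario simulation failed (missing fixed/variable split, coverage below baseline)."""


class CalibrationError(KhscmError):
    """Generator calibration could not reach the target within tolerance."""


class DataError(KhscmError):
    """Inconsistent study accounting (e.g. more exclusions than sampled facilities)."""
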