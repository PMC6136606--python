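"""Exception hierarchy shared by all modules."""

from __future__ import annotations


class LabSafeError(Exception):
    """Base class for user-facing errors (CLI exit code 1)."""


class SchemaParseError(LabSafeError):
    """The taxonomy document is not well-formed in the documented dialect."""


class TaxonomyValidationError(LabSafeError):
    """A parsed taxonomy violates structural invariants.

    Carries the full finding list so callers can report every violation,
    not just the first.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__(
            "taxonomy failed validation:\n"
            + "\n".join(str(f) for f in self.findings)
        )


class UnknownSubcategoryError(LabSafeError):
    """An assessment references subcategory ids absent from the taxonomy."""

    def __init__(self, ids):
        self.ids = sorted(ids)
        super().__init__(
            "responses reference unknown subcategories: " + ", ".join(self.ids)
        )


class PolicyError(LabSafeError):
    """Unknown blank-handling policy name."""


class FormatError(LabSafeError):
    """An interchange file (JSON / CSV / workbook) violates its schema."""


class ComparisonError(LabSafeError):
    """Invalid input to the multi-assessment comparison."""


class AggregationError(LabSafeError):
    """Invalid input to cohort aggregation."""


class ConfigError(LabSafeError):
    """Invalid synthetic-generator configuration."""
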