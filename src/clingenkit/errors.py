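"""Exception hierarchy for the toolkit.

Validation *violations* (data-quality findings) are ordinary values, not
exceptions; see :mod:`clingenkit.kb`.  Exceptions are reserved for contract
breaches: malformed files, identifier conflicts, stale interpretations.
"""


class ClinGenError(Exception):
    """Base class for all toolkit errors."""


class KBSchemaError(ClinGenError):
    """A knowledge-base table failed structural parsing (bad header, bad cell).

    Carries the offending row number and field where known.
    """

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class KBValidationError(ClinGenError):
    """A knowledge base failed invariant validation at load or after mutation."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:10])
        more = "" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)"
        super().__init__(f"{len(self.violations)} violation(s): {lines}{more}")


class UpsertError(ClinGenError):
    """An upsert's id preconditions were not met (add of existing id, etc.)."""


class GenotypeParseError(ClinGenError):
    """A genotype file or genotype token could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class ModelNotFoundError(ClinGenError):
    """Requested model_name has no definition of the required model_type."""


class KBIntegrityError(ClinGenError):
    """An association references knowledge-base content that does not exist."""


class StaleInterpretationError(ClinGenError):
    """A personal association set was computed against an older KB version."""


class ReplicaDivergenceError(ClinGenError):
    """A replica knowledge base is ahead of the central one (replicas are read-only)."""


class PayloadError(ClinGenError):
    """An exchange payload failed parsing or verification.

    ``code`` is one of: ``malformed-xml``, ``missing-attribute``,
    ``checksum-mismatch``, ``schema-mismatch``, ``unknown-payload-type``.
    """

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")
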