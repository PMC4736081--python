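"""Exception hierarchy for assembly simulation and design validation."""


class GBError(Exception):
    """Base class for all package errors."""


class SequenceError(GBError):
    """Malformed sequence or molecule."""


class AmbiguousDigestError(GBError):
    """Two cut windows overlap, so the digestion outcome is undefined."""

    def __init__(self, sites):
        self.sites = sites
        super().__init__(
            "ambiguous digest: overlapping cut windows at %s"
            % ", ".join(f"{a}-{b}" for a, b in sites)
        )


class LigationCapError(GBError):
    """Cycle enumeration exceeded the configured product cap."""


class AssemblyError(GBError):
    """No stable circular product could be assembled."""

    def __init__(self, message, unmatched_overhangs=()):
        self.unmatched_overhangs = tuple(unmatched_overhangs)
        if self.unmatched_overhangs:
            message += " (unmatched overhangs: %s)" % ", ".join(self.unmatched_overhangs)
        super().__init__(message)


class BraidViolationError(GBError):
    """Destination vector class does not alternate with the input class."""


class DomesticationError(GBError):
    """Sequence contains internal assembly-enzyme recognition sites."""

    def __init__(self, violations):
        self.violations = list(violations)
        detail = "; ".join(f"{e} on {s} strand at {o}" for e, s, o in self.violations)
        super().__init__(f"domestication violations: {detail}")


class DesignError(GBError):
    """Invalid guide-RNA design input (bad protospacer, policy rejection...)."""


class WorkflowError(GBError):
    """Workflow spec validation or execution failure."""
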