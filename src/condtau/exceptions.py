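"""Exception and warning types shared across the package."""


class CondtauError(Exception):
    """Base class for all condtau-specific errors."""


class EmptyWindowError(CondtauError):
    """No observation falls inside the kernel window around the conditioning point."""


class DegenerateWeightsError(CondtauError):
    """Kernel weights too concentrated for the weighted tau (1 - sum w_i^2 <= 0)."""


class ConstantCovariateError(CondtauError):
    """The covariate has zero spread; no bandwidth can be formed."""


class NoFeasibleBandwidthError(CondtauError):
    """No candidate bandwidth yields populated kernel windows."""


class DisjointWindowError(CondtauError):
    """Fewer than two conditioning points survive the disjoint-window thinning."""


class SingularCovarianceError(CondtauError):
    """R V R' is singular; the Wald quadratic form cannot be evaluated."""


class TiesWarning(UserWarning):
    """Tied response values detected; strict-inequality concordance is conservative."""
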