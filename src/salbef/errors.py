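"""Exception and warning types shared across the package."""


class SalbefError(Exception):
    """Base class for all package-specific errors."""


class DesignInfeasibleError(SalbefError):
    """An experimental design cannot be realized with the given strain library.

    Raised e.g. when a richness level exceeds the library size or when more
    distinct replicate communities are requested than C(n, N) allows.
    """


class SchemaError(SalbefError):
    """A tabular input does not conform to its declared CSV schema."""

    def __init__(self, path, missing=None, message=None):
        self.path = str(path)
        self.missing = list(missing) if missing else []
        if message is None:
            message = f"{self.path}: missing required column(s) {self.missing}"
        super().__init__(message)


class UnmappedTaxonError(SalbefError):
    """A genus in a composition table has no strain mapping in the design."""

    def __init__(self, genera):
        self.genera = sorted(genera)
        super().__init__(f"genus label(s) not present in the genus-strain map: {self.genera}")


class NoGrowthWarning(UserWarning):
    """All members of a mixture are below the detection floor at this salinity."""


class ClippedYieldWarning(UserWarning):
    """A selection tilt pushed a relative yield below zero; it was clipped to 0."""


class SingularFitWarning(UserWarning):
    """A mixed-model fit converged on the boundary or failed to converge."""
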