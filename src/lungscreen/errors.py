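"""Exception types shared across the package."""


class ConfigurationError(Exception):
    """A parameter table or fixture is missing a required stratum/cell."""


class RiskModelNotApplicable(ValueError):
    """The risk model is undefined for the given covariates (e.g. never-smokers)."""


class PopulationMismatchError(Exception):
    """Two scenario results were not produced on the same simulated population."""
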