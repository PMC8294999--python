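"""Exception types shared across the package."""


class SpecificationError(ValueError):
    """An input specification (phantom spec, config) violates its invariants."""


class SizeError(ValueError):
    """Array/image dimensions are incompatible with the requested operation."""


class InputError(ValueError):
    """An input value is invalid (empty list, out-of-range probability, ...)."""


class TrainingError(ValueError):
    """A learning routine received data it cannot be trained on."""


class DegeneratePartitionError(ValueError):
    """A level-set partition has an empty inside or outside region."""


class ConfigurationError(ValueError):
    """A pipeline configuration or model file is missing or malformed."""
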