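"""Exception hierarchy for the bbdesign package."""


class BBDesignError(Exception):
    """Base class for all package-specific errors."""


class CatalogIOError(BBDesignError, IOError):
    """A catalog file could not be read or written."""


class CatalogFormatError(BBDesignError, ValueError):
    """A catalog file was readable but structurally invalid (e.g. no parsable records)."""


class SchemaError(BBDesignError, ValueError):
    """A CSV catalog violates the expected schema (missing column, duplicate id)."""


class TruncationError(BBDesignError, ValueError):
    """A truncation transform produced a disconnected or unparsable structure."""

    def __init__(self, parent_id: str, message: str):
        self.parent_id = parent_id
        super().__init__(f"{parent_id}: {message}")


class AmbiguityError(BBDesignError, ValueError):
    """A building block has zero or multiple reaction sites for a coupling."""

    def __init__(self, bb_id: str, message: str):
        self.bb_id = bb_id
        super().__init__(f"{bb_id}: {message}")


class ReactionError(BBDesignError, ValueError):
    """An in-silico reaction transform failed to produce a valid product."""


class PoolExhaustedError(BBDesignError, ValueError):
    """A selection requested more members than the pool provides."""


class ConvergenceError(BBDesignError, RuntimeError):
    """An iterative procedure failed to reach its goal within its limits."""


class ConfigError(BBDesignError, ValueError):
    """An invalid configuration value (non-ascending thresholds, empty grammar, ...)."""
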