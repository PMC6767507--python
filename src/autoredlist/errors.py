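"""Exception types shared across the package."""


class AutoRedListError(Exception):
    """Base class for package-specific errors."""


class GridMismatchError(AutoRedListError):
    """Two rasters that must share a grid do not."""


class UnknownCodeError(AutoRedListError):
    """A land-cover raster contains a code absent from the crosswalk."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(f"land-cover codes missing from crosswalk: {self.codes}")


class UnsupportedTaxonError(AutoRedListError):
    """A predictor was asked for a taxon it does not cover.

    Density and dispersal are never predicted for bats (roost-driven clumped
    distributions make trait-based density meaningless), and population
    viability targets exist only for mammals.
    """


class InputValidationError(AutoRedListError):
    """A batch-run input file or record failed validation."""
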