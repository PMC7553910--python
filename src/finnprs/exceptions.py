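"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`FinnPrsError`, so callers can catch one type at pipeline level.
"""


class FinnPrsError(Exception):
    """Base class for all errors raised by finnprs."""


class ValidationError(FinnPrsError, ValueError):
    """Invalid input values (out-of-range probabilities, bad dosages, ...)."""


class EmptyPanelError(FinnPrsError):
    """SNP selection left no loci; a score cannot be computed."""


class MissingSnpError(FinnPrsError):
    """Panel loci absent from the genotype input."""

    def __init__(self, rsids):
        self.rsids = list(rsids)
        super().__init__(
            f"{len(self.rsids)} panel SNP(s) missing from genotypes: "
            + ", ".join(self.rsids[:10])
            + ("..." if len(self.rsids) > 10 else "")
        )


class AlleleMismatchError(FinnPrsError):
    """Alleles in the genotype input do not match the panel orientation."""


class FormatError(FinnPrsError):
    """Malformed input file (message carries the offending line number)."""
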