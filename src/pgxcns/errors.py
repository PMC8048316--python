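"""Structured exception hierarchy for the interpretation engine."""


class PgxError(Exception):
    """Base class for all engine errors."""


class PanelLoadError(PgxError):
    """The panel configuration failed validation (duplicate rsid, broken
    reference, excluded evidence level, ...)."""


class GenotypeParseError(PgxError):
    """A genotype cell or VCF record could not be converted to a dosage."""


class AlleleMismatchError(GenotypeParseError):
    """Observed alleles cannot be reconciled with the panel ref/alt pair."""


class InconsistentGenotypeError(PgxError):
    """No haplotype pair is consistent with the observed dosages at a gene's
    star-defining SNPs."""


class ClassificationError(PgxError):
    """A diplotype could not be mapped to a metabolizer phenotype."""


class DegenerateTableError(PgxError):
    """A contingency table has a zero row or column margin."""
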