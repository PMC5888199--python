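"""Core in-memory containers: genotype and expression matrices.

Both containers pair a samples-by-features :class:`pandas.DataFrame` of values
with a feature-annotation frame, so every downstream operation can rely on
aligned sample ids and 1-based genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default chromosomal interval excluded from risk-locus analyses (the
#: extended HLA region on chromosome 6, 1-based inclusive coordinates).
HLA_REGION = ("6", 25_000_000, 35_000_000)

#: Forward-only normalization states for expression data.
EXPRESSION_STATES = ("raw", "normalized", "batch_corrected")


@dataclass
class GenotypeMatrix:
    """Additive allele dosages for a cohort.

    Parameters
    ----------
    dosages
        samples x variants frame; values in [0, 2], NaN marks a missing call.
    variants
        Per-variant metadata indexed by rsid. Required columns: ``chrom``,
        ``pos`` (1-based), ``ref``, ``alt``. QC columns (``maf``, ``info``,
        ``call_rate``) are added by :mod:`permqtl.genoqc`.
    posteriors
        Optional genotype posterior triples, shape (n_samples, n_variants, 3),
        each triple summing to 1. Used for imputation INFO scores.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    posteriors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValidationError("variant annotation does not match dosage columns")
        for col in ("chrom", "pos"):
            if col not in self.variants.columns:
                raise ValidationError(f"variant annotation missing column '{col}'")
        if self.posteriors is not None:
            expect = (self.n_samples, self.n_variants, 3)
            if tuple(self.posteriors.shape) != expect:
                raise ValidationError(
                    f"posterior array shape {self.posteriors.shape}, expected {expect}"
                )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample/variant ids."""
        dos = self.dosages
        post = self.posteriors
        if samples is not None:
            samples = list(samples)
            idx = [self.dosages.index.get_loc(s) for s in samples]
            dos = dos.loc[samples]
            if post is not None:
                post = post[idx]
        var = self.variants
        if variants is not None:
            variants = list(variants)
            cols = [self.dosages.columns.get_loc(v) for v in variants]
            dos = dos[variants]
            var = var.loc[variants]
            if post is not None:
                post = post[:, cols]
        return GenotypeMatrix(dos, var.copy(), post)


@dataclass
class ExpressionMatrix:
    """Expression intensities with probe annotation and a normalization state.

    ``values`` is samples x probes; ``probes`` is indexed by probe id with
    columns ``gene_symbol``, ``chrom``, ``start_pos`` (1-based probe start)
    and optional ``blacklisted``. Probes with missing coordinates are carried
    but excluded from cis/trans classification.
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.probes.index):
            raise ValidationError("probe annotation does not match value columns")
        if self.probes.index.duplicated().any():
            dups = sorted(self.probes.index[self.probes.index.duplicated()])
            raise ValidationError(f"duplicate probe ids: {dups}")
        if self.state not in EXPRESSION_STATES:
            raise ValidationError(f"unknown normalization state '{self.state}'")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_state(self, state: str) -> "ExpressionMatrix":
        """Advance the normalization state; transitions are forward-only."""
        if EXPRESSION_STATES.index(state) < EXPRESSION_STATES.index(self.state):
            raise ValidationError(
                f"cannot move state backwards: {self.state} -> {state}"
            )
        return replace(self, state=state)

    def subset(self, samples=None, probes=None) -> "ExpressionMatrix":
        vals = self.values
        ann = self.probes
        if samples is not None:
            vals = vals.loc[list(samples)]
        if probes is not None:
            probes = list(probes)
            vals = vals[probes]
            ann = ann.loc[probes]
        return ExpressionMatrix(vals, ann.copy(), self.state)
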