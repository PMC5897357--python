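"""Sparse genotype container shared across the pipeline.

Rare-variant cohorts are overwhelmingly homozygous reference, so dosages are
held as a scipy CSC matrix (samples x variants) of alternate-allele counts:
0/1/2 for diploid sites and 0/1 for hemizygous male X genotypes.  Missing
genotypes are a second sparse boolean mask (a missing entry overrides the
dosage).  Variant columns are aligned with the annotation table row order;
sample rows with the sample sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    dosage: sparse.csc_matrix          # n_samples x n_variants, int8
    missing: sparse.csc_matrix | None = None
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosage = sparse.csc_matrix(self.dosage, dtype=np.int8)
        if self.missing is None:
            self.missing = sparse.csc_matrix(self.dosage.shape, dtype=bool)
        else:
            self.missing = sparse.csc_matrix(self.missing, dtype=bool)
        if self.missing.shape != self.dosage.shape:
            raise ValueError("missing mask shape does not match dosage matrix")
        if self.missing.nnz:
            # canonical form: a missing entry has dosage 0 (mask wins)
            self.dosage = sparse.csc_matrix(
                self.dosage - self.dosage.multiply(self.missing), dtype=np.int8)
            self.dosage.eliminate_zeros()

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def column(self, j: int, samples=None) -> np.ndarray:
        """Dense dosage for variant j (missing as -1), optionally row-subset."""
        col = np.asarray(self.dosage[:, j].todense()).ravel().astype(np.int16)
        miss = np.asarray(self.missing[:, j].todense()).ravel()
        col[miss] = -1
        if samples is not None:
            col = col[samples]
        return col

    def dense(self, rows=None, cols=None, missing_as: int = 0) -> np.ndarray:
        """Dense block of dosages; missing entries replaced by ``missing_as``."""
        d = self.dosage
        m = self.missing
        if cols is not None:
            d = d[:, cols]
            m = m[:, cols]
        if rows is not None:
            d = d[rows, :]
            m = m[rows, :]
        out = np.asarray(d.todense(), dtype=float)
        out[np.asarray(m.todense())] = missing_as
        return out

    def carriers_of(self, j: int) -> np.ndarray:
        """Row indices of samples with >= 1 alternate allele at variant j."""
        start, stop = self.dosage.indptr[j], self.dosage.indptr[j + 1]
        return self.dosage.indices[start:stop]
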