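"""Random-forest classifier exposing OOB error and standardized importance.

The pathway tests consume exactly two quantities from a forest: the
out-of-bag (OOB) prediction error — the fraction of samples misclassified by
the majority vote of the trees in whose bootstrap sample they did not appear
— and the Breiman-style standardized permutation variable importance

    Z_j = mean_t(d_tj) / ( sd_t(d_tj) / sqrt(n_trees) ),

where d_tj is tree t's OOB accuracy drop after permuting SNP j's values
within its OOB set.  Z_j is defined as 0 when sd_t(d_tj) = 0 (e.g. for a
constant SNP).  This is the scaled importance that the two-stage test
thresholds at 1.64 (one-tailed normal 0.05); note it differs from the Gini
or unscaled mean-decrease-accuracy importances most libraries report.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import fit_forest_kernel
from .io import GenotypeMatrix

__all__ = ["ForestConfig", "ForestFit", "fit_forest", "snp_identity_hash"]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters.

    Defaults follow randomForest / Random Jungle conventions: 500 trees,
    mtry = floor(sqrt(p)), terminal nodes grown to purity, n-out-of-n
    bootstrap with replacement.
    """

    n_trees: int = 500
    mtry: int | str = "sqrt"
    min_node_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def mtry_count(self, p: int) -> int:
        """Number of split candidates sampled per node."""
        if self.mtry == "sqrt":
            return max(1, math.floor(math.sqrt(p)))
        return min(int(self.mtry), p)


@dataclass
class ForestFit:
    """OOB error rate and per-SNP standardized importance from one forest."""

    oob_error: float
    importance_z: np.ndarray
    oob_votes: np.ndarray
    n_trees_used: int
    snp_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "oob_error": self.oob_error,
                "n_trees_used": self.n_trees_used,
                "snp_ids": self.snp_ids,
                "importance_z": [float(z) for z in self.importance_z],
                "oob_case_vote_fraction": [
                    None if np.isnan(v) else float(v) for v in self.oob_votes
                ],
            }
        )


def snp_identity_hash(snp_ids: Sequence[str]) -> np.ndarray:
    """Stable 64-bit hash per SNP id (blake2b), independent of column order."""
    out = np.empty(len(snp_ids), dtype=np.uint64)
    for j, sid in enumerate(snp_ids):
        digest = hashlib.blake2b(sid.encode(), digest_size=8).digest()
        out[j] = np.uint64(int.from_bytes(digest, "little"))
    return out


def fit_forest(
    matrix: GenotypeMatrix,
    snp_subset: Sequence[int] | None = None,
    config: ForestConfig | None = None,
    phenotype: np.ndarray | None = None,
    compute_importance: bool = True,
    colhash: np.ndarray | None = None,
) -> ForestFit:
    """Fit a forest on a subset of SNP columns and collect OOB statistics.

    Parameters
    ----------
    snp_subset:
        Column indices into ``matrix.dosages``; ``None`` means all SNPs.
    phenotype:
        Optional replacement 0/1 label vector (used by the permutation
        tests); defaults to ``matrix.phenotype``.
    compute_importance:
        Skip the (costly) permutation importance when only the OOB error is
        needed.  Does not affect the grown trees or the OOB error.
    colhash:
        Precomputed :func:`snp_identity_hash` of all matrix columns, to avoid
        rehashing in tight loops.
    """
    config = config or ForestConfig()
    y = matrix.phenotype if phenotype is None else np.asarray(phenotype, np.int8)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("phenotype must contain both cases and controls")
    if matrix.missing_mask is not None and matrix.missing_mask.any():
        raise ValueError("matrix contains missing genotypes; impute first")
    if snp_subset is None:
        cols = np.arange(matrix.n_snps, dtype=np.int64)
    else:
        cols = np.asarray(snp_subset, dtype=np.int64)
    if cols.size == 0:
        raise ValueError("snp_subset must be non-empty")
    if colhash is None:
        colhash = snp_identity_hash(matrix.snp_ids)
    # canonical (identity-hash-sorted) feature order: makes the fit exactly
    # invariant to the column order of the input matrix
    order = np.argsort(colhash[cols], kind="stable")
    sorted_cols = cols[order]
    oob_error, z_sorted, votes = fit_forest_kernel(
        matrix.dosages,
        y,
        sorted_cols,
        colhash,
        config.n_trees,
        config.min_node_size,
        config.mtry_count(cols.size),
        np.uint64(config.seed),
        compute_importance,
    )
    z = np.empty_like(z_sorted)
    z[order] = z_sorted
    return ForestFit(
        oob_error=float(oob_error),
        importance_z=z,
        oob_votes=votes,
        n_trees_used=config.n_trees,
        snp_ids=[matrix.snp_ids[c] for c in cols],
    )
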