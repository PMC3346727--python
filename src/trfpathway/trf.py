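"""Two-stage random-forest pathway association test (TRF-pathway).

For one pathway's SNP set the algorithm is:

1. fit a forest on all pathway SNPs and compute each SNP's standardized
   permutation importance Z;
2. keep the SNPs with Z strictly greater than a threshold (default 1.64,
   the one-tailed normal 0.05 point) and refit a forest on them;
3. the stage-2 OOB prediction error is the pathway score R (lower = more
   class signal);
4. permute the case/control labels K times, rerunning *both* stages inside
   every permutation — the stage-1 selection is part of the statistic, so
   re-running it under each permutation is what keeps the null distribution
   of R exchangeable and the test free of selection bias;
5. p = (1 + #{R_i <= R}) / (K + 1).

With no threshold the two stages collapse and the procedure is the
single-stage RF-pathway test (one forest, its OOB error, same permutation
scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forest import ForestConfig, fit_forest, snp_identity_hash
from .io import (
    GeneAnnotation,
    GenotypeMatrix,
    PathwayDefinition,
    PathwaySnpSet,
    SnpAnnotation,
    map_snps_to_pathway,
)
from .utils import derive_seed

__all__ = [
    "TrfConfig",
    "PathwayTestResult",
    "trf_pathway_test",
    "rf_pathway_test",
    "permutation_pvalue",
    "run_pathway_collection",
]

#: One-tailed standard-normal 5% critical value used as the default
#: importance cut between the two stages.
DEFAULT_IMPORTANCE_THRESHOLD = 1.64


@dataclass(frozen=True)
class TrfConfig:
    """Configuration of the two-stage test.

    ``importance_threshold=None`` disables stage 2 entirely (single-stage
    RF-pathway).  ``fallback_policy`` governs the case where no SNP exceeds
    the threshold: ``"all_snps"`` keeps the full stage-1 set for that fit
    (observed or permuted alike, preserving exchangeability); ``"top_one"``
    keeps only the highest-Z SNP.
    """

    importance_threshold: float | None = DEFAULT_IMPORTANCE_THRESHOLD
    n_permutations: int = 2000
    forest: ForestConfig = field(default_factory=ForestConfig)
    window_kb: float = 20.0
    fallback_policy: str = "all_snps"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.importance_threshold is not None and not np.isfinite(
            self.importance_threshold
        ):
            raise ValueError("importance_threshold must be finite or None")
        if self.fallback_policy not in ("all_snps", "top_one"):
            raise ValueError("fallback_policy must be 'all_snps' or 'top_one'")

    @property
    def seed(self) -> int:
        return self.forest.seed


@dataclass
class PathwayTestResult:
    """Observed score, permutation null sample and p-value for one pathway.

    For the forest tests ``R`` is the stage-2 OOB error (small R = signal);
    for the set-based comparator ``R`` holds the mean-chi-square statistic
    (large = signal) and the p-value direction is reversed accordingly.
    """

    pathway_id: str
    n_snps_stage1: int
    n_snps_stage2: int
    R: float
    R_perm: np.ndarray
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_snps_stage2 > self.n_snps_stage1:
            raise ValueError("stage-2 SNP count cannot exceed stage 1")


def permutation_pvalue(R: float, R_perm: Sequence[float]) -> float:
    """Add-one permutation p-value, (1 + #{R_i <= R}) / (K + 1).

    Ties count as "at least as extreme"; the estimate is always in
    [1/(K+1), 1], never zero.
    """
    R_perm = np.asarray(R_perm, dtype=float)
    if R_perm.size == 0:
        raise ValueError("R_perm must be non-empty")
    return (1 + int((R_perm <= R).sum())) / (R_perm.size + 1)


def _two_stage_score(
    matrix: GenotypeMatrix,
    cols: np.ndarray,
    y: np.ndarray,
    config: TrfConfig,
    forest_seed: int,
    colhash: np.ndarray,
) -> tuple[float, int]:
    """Run stages 1-2 on labels ``y``; return (OOB error, stage-2 SNP count).

    The identical code path serves the observed data and every permutation.
    """
    fcfg = ForestConfig(
        n_trees=config.forest.n_trees,
        mtry=config.forest.mtry,
        min_node_size=config.forest.min_node_size,
        seed=forest_seed,
    )
    threshold = config.importance_threshold
    fit1 = fit_forest(
        matrix,
        cols,
        fcfg,
        phenotype=y,
        compute_importance=threshold is not None,
        colhash=colhash,
    )
    if threshold is None:
        return fit1.oob_error, cols.size
    selected = cols[fit1.importance_z > threshold]
    if selected.size == cols.size:
        # same subset + same seed would regrow the identical forest
        return fit1.oob_error, cols.size
    if selected.size == 0:
        if config.fallback_policy == "all_snps":
            return fit1.oob_error, cols.size
        selected = cols[np.argmax(fit1.importance_z) : np.argmax(fit1.importance_z) + 1]
    fit2 = fit_forest(
        matrix, selected, fcfg, phenotype=y, compute_importance=False, colhash=colhash
    )
    return fit2.oob_error, selected.size


def trf_pathway_test(
    matrix: GenotypeMatrix, snpset: PathwaySnpSet, config: TrfConfig | None = None
) -> PathwayTestResult:
    """Run the TRF-pathway permutation test for one pathway SNP set."""
    config = config or TrfConfig()
    if len(snpset) == 0:
        raise ValueError(f"pathway {snpset.pathway_id}: empty SNP set")
    if not matrix.has_both_classes():
        raise ValueError("phenotype must contain both cases and controls")
    cols = np.asarray(snpset.snp_indices, dtype=np.int64)
    colhash = snp_identity_hash(matrix.snp_ids)
    seed = config.seed
    K = config.n_permutations

    R, n2 = _two_stage_score(
        matrix, cols, matrix.phenotype, config, derive_seed(seed, 1, 0), colhash
    )
    R_perm = np.empty(K, dtype=float)
    for i in range(1, K + 1):
        rng = np.random.default_rng(derive_seed(seed, 2, i))
        y_perm = rng.permutation(matrix.phenotype)
        R_perm[i - 1], _ = _two_stage_score(
            matrix, cols, y_perm, config, derive_seed(seed, 1, i), colhash
        )
    return PathwayTestResult(
        pathway_id=snpset.pathway_id,
        n_snps_stage1=cols.size,
        n_snps_stage2=n2,
        R=R,
        R_perm=R_perm,
        p_value=permutation_pvalue(R, R_perm),
        seed=seed,
    )


def rf_pathway_test(
    matrix: GenotypeMatrix, snpset: PathwaySnpSet, config: TrfConfig | None = None
) -> PathwayTestResult:
    """Single-stage RF-pathway test (no importance threshold)."""
    config = config or TrfConfig()
    from dataclasses import replace

    return trf_pathway_test(matrix, snpset, replace(config, importance_threshold=None))


def run_pathway_collection(
    matrix: GenotypeMatrix,
    pathways: Sequence[PathwayDefinition],
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpAnnotation],
    config: TrfConfig | None = None,
    methods: Sequence[str] = ("trf",),
    set_config=None,
    progress=None,
) -> pd.DataFrame:
    """Test every mappable pathway; return a table sorted by p-value.

    Columns mirror the usual pathway-report layout: pathway id/name, genes
    matched, SNPs mapped, stage-2 SNP count, one p-value column per
    requested method (``trf_p``, ``rf_p``, ``plink_p``) plus a Bonferroni
    column for the first method.  The Bonferroni adjustment is reported but
    conservative: pathways share genes, so the tests are not independent.
    Pathways mapping to zero SNPs appear with ``skipped=True`` and NaN
    p-values.
    """
    config = config or TrfConfig()
    rows = []
    for pw in pathways:
        snpset = map_snps_to_pathway(pw, genes, snps, config.window_kb)
        row: dict = {
            "pathway": pw.pathway_id,
            "name": pw.name,
            "n_genes": snpset.n_genes_matched,
            "n_snps": len(snpset),
            "n_snps_stage2": np.nan,
            "skipped": len(snpset) == 0,
        }
        if len(snpset) > 0:
            for method in methods:
                if method == "trf":
                    res = trf_pathway_test(matrix, snpset, config)
                    row["trf_p"] = res.p_value
                    row["n_snps_stage2"] = res.n_snps_stage2
                elif method == "rf":
                    res = rf_pathway_test(matrix, snpset, config)
                    row["rf_p"] = res.p_value
                elif method == "setbased":
                    from .setbased import SetTestConfig, set_based_test

                    scfg = set_config or SetTestConfig(
                        n_permutations=config.n_permutations, seed=config.seed
                    )
                    res = set_based_test(matrix, snpset, scfg)
                    row["plink_p"] = res.p_value
                else:
                    raise ValueError(f"unknown method {method!r}")
        rows.append(row)
        if progress is not None:
            progress(pw.pathway_id, row)
    table = pd.DataFrame(rows)
    pcol = {"trf": "trf_p", "rf": "rf_p", "setbased": "plink_p"}[methods[0]]
    n_tested = int((~table["skipped"]).sum())
    if pcol in table.columns:
        table["bonferroni_p"] = np.minimum(table[pcol] * n_tested, 1.0)
        table = table.sort_values(pcol, na_position="last", kind="mergesort")
    return table.reset_index(drop=True)
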