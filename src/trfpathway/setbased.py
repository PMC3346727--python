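"""PLINK-style set-based association test (the comparator method).

The pathway statistic is the mean of the 1-df allelic chi-square statistics
over tag SNPs whose single-SNP p-value is below a cut (default 0.05); tag
SNPs are chosen greedily by significance with LD pruning at a pairwise r-sq
threshold (default 0.5).  Significance comes from phenotype permutation with
the entire pipeline — chi-squares, tag selection, statistic — recomputed
inside every permutation.  Large statistic = more significant, the opposite
direction to the forest tests' error score.

r-sq here is the squared Pearson correlation of the dosage vectors
(composite-genotype LD); it depends on genotypes only, never on phenotype,
so the pairwise matrix is computed once and reused across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GenotypeMatrix, PathwaySnpSet
from .trf import PathwayTestResult
from .utils import derive_seed

__all__ = [
    "SetTestConfig",
    "allelic_chisq",
    "allelic_chisq_all",
    "pairwise_r2",
    "pairwise_r2_matrix",
    "select_tag_snps",
    "set_based_test",
]


@dataclass(frozen=True)
class SetTestConfig:
    """Tag-pruning threshold, per-SNP p cut, and permutation count."""

    r2_threshold: float = 0.5
    snp_p_cut: float = 0.05
    n_permutations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        if not 0.0 < self.snp_p_cut <= 1.0:
            raise ValueError("snp_p_cut must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def allelic_chisq(dosages: np.ndarray, phenotype: np.ndarray) -> tuple[float, float]:
    """1-df Pearson chi-square on the 2x2 allele-count table, no correction.

    Allele counts per class are (sum of dosages, 2n - sum of dosages); a
    monomorphic SNP returns (0, 1) by convention.
    """
    stat = allelic_chisq_all(dosages[:, None], phenotype)[0]
    p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, 1))
    return float(stat), p


def allelic_chisq_all(G: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Vectorized allelic chi-square statistics for every column of ``G``."""
    y = np.asarray(phenotype, dtype=np.float64)
    n1 = y.sum()
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("phenotype must contain both cases and controls")
    Gf = G.astype(np.float64, copy=False)
    a_case = y @ Gf                       # minor-allele count in cases
    a_all = Gf.sum(axis=0)
    a_ctrl = a_all - a_case
    t_case, t_ctrl = 2.0 * n1, 2.0 * n0
    N = t_case + t_ctrl
    minor = a_all
    major = N - a_all
    # chi2 = N (ad - bc)^2 / (r1 r2 c1 c2) on [[a_case, t_case-a_case], ...]
    num = N * (a_case * (t_ctrl - a_ctrl) - (t_case - a_case) * a_ctrl) ** 2
    den = t_case * t_ctrl * minor * major
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2


def pairwise_r2(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns; constant -> 0."""
    a = np.asarray(snp_a, dtype=np.float64)
    b = np.asarray(snp_b, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("columns must have the same length")
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def pairwise_r2_matrix(G: np.ndarray) -> np.ndarray:
    """All-pairs dosage r-sq; rows/cols of constant SNPs are 0."""
    Gf = G.astype(np.float64, copy=False)
    sd = Gf.std(axis=0)
    ok = sd > 0
    r2 = np.zeros((G.shape[1], G.shape[1]))
    if ok.sum() >= 2:
        sub = np.corrcoef(Gf[:, ok], rowvar=False)
        r2[np.ix_(ok, ok)] = sub * sub
    elif ok.sum() == 1:
        j = int(np.nonzero(ok)[0][0])
        r2[j, j] = 1.0
        return r2
    np.fill_diagonal(r2, np.where(ok, 1.0, 0.0))
    return r2


def _greedy_tags(chi2: np.ndarray, r2: np.ndarray, r2_threshold: float) -> list[int]:
    """Greedy significance-ordered LD pruning; ties -> smaller column index."""
    remaining = np.ones(chi2.size, dtype=bool)
    tags: list[int] = []
    neg = -chi2  # argmin over -chi2 = most significant, first index on ties
    while remaining.any():
        cand = np.where(remaining, neg, np.inf)
        j = int(np.argmin(cand))
        tags.append(j)
        remaining &= r2[j] < r2_threshold
        remaining[j] = False
    return tags


def select_tag_snps(
    G: np.ndarray,
    phenotype: np.ndarray,
    config: SetTestConfig | None = None,
    r2: np.ndarray | None = None,
) -> list[int]:
    """Ordered tag list for the columns of ``G``.

    Repeat until no SNP remains: emit the remaining SNP with the largest
    chi-square (smallest p; ties toward the smaller column index) and drop
    every remaining SNP with r-sq >= ``r2_threshold`` to it.
    """
    config = config or SetTestConfig()
    if G.shape[1] == 0:
        raise ValueError("SNP set must be non-empty")
    chi2 = allelic_chisq_all(G, phenotype)
    if r2 is None:
        r2 = pairwise_r2_matrix(G)
    return _greedy_tags(chi2, r2, config.r2_threshold)


def _set_statistic(
    chi2: np.ndarray, r2: np.ndarray, config: SetTestConfig
) -> float:
    tags = _greedy_tags(chi2, r2, config.r2_threshold)
    crit = stats.chi2.isf(config.snp_p_cut, 1)
    qual = [j for j in tags if chi2[j] > crit]
    if not qual:
        return 0.0
    return float(np.mean(chi2[qual]))


def set_based_test(
    matrix: GenotypeMatrix,
    snpset: PathwaySnpSet,
    config: SetTestConfig | None = None,
) -> PathwayTestResult:
    """Permutation p-value for the mean-significant-chi-square set statistic.

    ``R`` in the returned result holds the observed statistic S (larger =
    more significant); ``n_snps_stage2`` counts the observed tag SNPs.
    """
    config = config or SetTestConfig()
    if len(snpset) == 0:
        raise ValueError(f"pathway {snpset.pathway_id}: empty SNP set")
    if not matrix.has_both_classes():
        raise ValueError("phenotype must contain both cases and controls")
    cols = np.asarray(snpset.snp_indices, dtype=np.int64)
    G = matrix.dosages[:, cols]
    y = matrix.phenotype
    r2 = pairwise_r2_matrix(G)

    chi2_obs = allelic_chisq_all(G, y)
    S_obs = _set_statistic(chi2_obs, r2, config)
    n_tags = len(_greedy_tags(chi2_obs, r2, config.r2_threshold))

    K = config.n_permutations
    S_perm = np.empty(K)
    for i in range(1, K + 1):
        rng = np.random.default_rng(derive_seed(config.seed, 4, i))
        y_perm = rng.permutation(y)
        S_perm[i - 1] = _set_statistic(
            allelic_chisq_all(G, y_perm), r2, config
        )
    p = (1 + int((S_perm >= S_obs).sum())) / (K + 1)
    return PathwayTestResult(
        pathway_id=snpset.pathway_id,
        n_snps_stage1=cols.size,
        n_snps_stage2=n_tags,
        R=S_obs,
        R_perm=S_perm,
        p_value=p,
        seed=config.seed,
    )
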