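"""Case-control SNP simulation with LD blocks and an epistatic disease model.

Genotypes come from a Gaussian-copula block simulator: within each block
(one block per "gene") a latent exchangeable-correlation multivariate normal
is thresholded at each SNP's minor-allele-frequency quantile to give one
haplotype; two independent haplotypes per individual sum to the 0/1/2
dosage.  Marginally each SNP is in Hardy-Weinberg equilibrium at its target
MAF; between blocks SNPs are independent.

Disease status follows a logistic penetrance on dominant-coded causal loci
(X_i = 1 iff the individual carries at least one minor allele at locus i):

    P(case | X) = expit(a + b1 X1 + b2 X2 + b3 X3
                        + b4 X1X2 + b5 X1X3 + b6 X2X3 + b7 X1X2X3
                        [+ b_extra X4])

with the intercept `a` solved so the population prevalence matches its
target, averaging over the 2^L causal-carrier configurations under HWE and
independence (the causal loci sit in different blocks).

Effect models: "M1" is main-effects-only (b1-b3 = 0.92); "M2"/"M3"/"M4" are
multiplicative schemes b1-b3 = phi, b4-b6 = 2 phi, b7 = 3 phi with phi =
0.18 / 0.22 / 0.26, so the joint odds effect of two or three loci is the
product of the marginal ones; "null" sets every coefficient to zero.
Scenario presets: S1 = 1000/1000 samples, 50 genes, 1038 SNPs, prevalence
1%, causal MAFs .25/.15/.15; S2 halves the samples; S3 raises prevalence to
5%; S4 is a larger pathway (100 genes, 1527 SNPs) with a fourth,
main-effect-only causal locus at MAF .25.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .forest import ForestConfig
from .io import GenotypeMatrix, PathwaySnpSet
from .setbased import SetTestConfig, set_based_test
from .trf import TrfConfig, rf_pathway_test, trf_pathway_test
from .utils import derive_seed

__all__ = [
    "LdBlockModel",
    "DiseaseModel",
    "ScenarioSpec",
    "EffectModelSpec",
    "simulate_genotypes",
    "penetrance",
    "solve_alpha",
    "simulate_case_control",
    "run_experiment",
    "ExperimentResult",
]

#: Default within-block latent correlation; gives mean pairwise dosage
#: r-sq around 0.45 within a block, a realistic within-gene LD level.
DEFAULT_RHO = 0.7


@dataclass(frozen=True)
class LdBlockModel:
    """Block-structured SNP panel: MAFs plus within-block correlation."""

    n_snps: int
    block_sizes: tuple[int, ...]
    within_block_rho: float = DEFAULT_RHO
    maf_range: tuple[float, float] = (0.05, 0.45)
    seed: int = 0
    mafs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_snps:
            raise ValueError("block_sizes must sum to n_snps")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high < 0.5")
        if self.mafs is not None and len(self.mafs) != self.n_snps:
            raise ValueError("mafs length must equal n_snps")

    def snp_mafs(self) -> np.ndarray:
        """Per-SNP target MAFs (explicit, or drawn once from maf_range)."""
        if self.mafs is not None:
            return np.asarray(self.mafs, dtype=float)
        rng = np.random.default_rng(derive_seed(self.seed, 20))
        lo, hi = self.maf_range
        return rng.uniform(lo, hi, size=self.n_snps)


@dataclass(frozen=True)
class DiseaseModel:
    """Penetrance-model parameters for 3 (or 4) dominant-coded causal loci."""

    causal_snp_indices: tuple[int, ...]
    causal_mafs: tuple[float, ...]
    alpha: float
    beta: tuple[float, ...]          # b1..b7 for the three interacting loci
    prevalence: float
    beta_extra: float | None = None  # main effect of an optional 4th locus

    def __post_init__(self) -> None:
        if len(self.beta) != 7:
            raise ValueError("beta must have 7 entries (b1..b7)")
        n_loci = len(self.causal_snp_indices)
        if n_loci not in (3, 4):
            raise ValueError("3 or 4 causal loci supported")
        if len(self.causal_mafs) != n_loci:
            raise ValueError("causal_mafs must match causal_snp_indices")
        if n_loci == 4 and self.beta_extra is None:
            raise ValueError("beta_extra required with a 4th causal locus")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


def _linear_predictor(
    X: np.ndarray, beta: Sequence[float], beta_extra: float | None
) -> np.ndarray:
    """Log-odds contribution of the causal-carrier configuration X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    b = beta
    eta = (
        b[0] * x1 + b[1] * x2 + b[2] * x3
        + b[3] * x1 * x2 + b[4] * x1 * x3 + b[5] * x2 * x3
        + b[6] * x1 * x2 * x3
    )
    if X.shape[1] == 4:
        if beta_extra is None:
            raise ValueError("4-column X requires beta_extra")
        eta = eta + beta_extra * X[:, 3]
    return eta


def penetrance(X: np.ndarray, model: DiseaseModel) -> np.ndarray | float:
    """P(case | X) for dominant-coded causal configuration(s) X."""
    X_arr = np.asarray(X)
    eta = model.alpha + _linear_predictor(X_arr, model.beta, model.beta_extra)
    out = expit(eta)
    return float(out[0]) if X_arr.ndim == 1 else out


def solve_alpha(
    betas: Sequence[float],
    causal_mafs: Sequence[float],
    prevalence: float,
    beta_extra: float | None = None,
) -> float:
    """Intercept making the population prevalence hit its target.

    Averages the logistic penetrance over the 2^L carrier configurations,
    with carrier probabilities P(X_i = 1) = 1 - (1 - maf_i)^2 from HWE and
    between-locus independence; solved by bisection on [-50, 50].
    """
    mafs = np.asarray(causal_mafs, dtype=float)
    if not ((mafs > 0) & (mafs <= 0.5)).all():
        raise ValueError("causal MAFs must be in (0, 0.5]")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    L = mafs.size
    q = 1.0 - (1.0 - mafs) ** 2  # carrier probability per locus
    configs = np.array(list(itertools.product((0, 1), repeat=L)), dtype=float)
    probs = np.prod(np.where(configs == 1, q, 1.0 - q), axis=1)
    etas = _linear_predictor(configs, betas, beta_extra)

    def f(a: float) -> float:
        return float(probs @ expit(a + etas)) - prevalence

    lo, hi = -50.0, 50.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no prevalence-matching intercept in [-50, 50]")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


@dataclass(frozen=True)
class ScenarioSpec:
    """Sample sizes, pathway size and disease-model frame of one scenario."""

    name: str
    n_cases: int
    n_controls: int
    n_genes: int
    n_snps: int
    prevalence: float
    causal_mafs: tuple[float, ...]

    _PRESETS = {
        "S1": (1000, 1000, 50, 1038, 0.01, (0.25, 0.15, 0.15)),
        "S2": (500, 500, 50, 1038, 0.01, (0.25, 0.15, 0.15)),
        "S3": (1000, 1000, 50, 1038, 0.05, (0.25, 0.15, 0.15)),
        "S4": (1000, 1000, 100, 1527, 0.01, (0.25, 0.15, 0.15, 0.25)),
    }

    @classmethod
    def preset(cls, name: str) -> "ScenarioSpec":
        if name not in cls._PRESETS:
            raise ValueError(f"unknown scenario {name!r}")
        return cls(name, *cls._PRESETS[name])

    def scaled(
        self, n_cases: int, n_controls: int, n_genes: int, n_snps: int
    ) -> "ScenarioSpec":
        """Same disease model at a reduced Monte-Carlo problem size."""
        return replace(
            self,
            name=f"{self.name}-scaled",
            n_cases=n_cases,
            n_controls=n_controls,
            n_genes=n_genes,
            n_snps=n_snps,
        )


@dataclass(frozen=True)
class EffectModelSpec:
    """Named effect model; ``phi`` applies to the multiplicative models."""

    name: str
    phi: float | None = None

    _PHI = {"M2": 0.18, "M3": 0.22, "M4": 0.26}

    @classmethod
    def preset(cls, name: str) -> "EffectModelSpec":
        if name in ("null", "M1"):
            return cls(name)
        if name in cls._PHI:
            return cls(name, cls._PHI[name])
        raise ValueError(f"unknown effect model {name!r}")

    def betas(self) -> tuple[float, ...]:
        """(b1..b7) for the three interacting loci."""
        if self.name == "null":
            return (0.0,) * 7
        if self.name == "M1":
            return (0.92, 0.92, 0.92, 0.0, 0.0, 0.0, 0.0)
        phi = self.phi if self.phi is not None else self._PHI[self.name]
        return (phi, phi, phi, 2 * phi, 2 * phi, 2 * phi, 3 * phi)

    def beta_extra(self) -> float:
        """Main effect of the optional 4th locus (matches the model's
        main-effect size; zero under the null)."""
        if self.name == "null":
            return 0.0
        if self.name == "M1":
            return 0.92
        return self.phi if self.phi is not None else self._PHI[self.name]


def _partition_blocks(n_snps: int, n_blocks: int) -> tuple[int, ...]:
    base, extra = divmod(n_snps, n_blocks)
    return tuple(base + (1 if b < extra else 0) for b in range(n_blocks))


def build_panel(
    scenario: ScenarioSpec,
    rho: float = DEFAULT_RHO,
    seed: int = 0,
) -> tuple[LdBlockModel, tuple[int, ...]]:
    """SNP panel for a scenario: one LD block per gene, causal loci in
    distinct blocks (mid-block), causal MAFs pinned to the scenario's."""
    if scenario.n_genes < len(scenario.causal_mafs):
        raise ValueError(
            f"{scenario.name}: needs at least {len(scenario.causal_mafs)} gene "
            "blocks to place the causal loci in distinct genes"
        )
    sizes = _partition_blocks(scenario.n_snps, scenario.n_genes)
    ld = LdBlockModel(
        n_snps=scenario.n_snps,
        block_sizes=sizes,
        within_block_rho=rho,
        seed=seed,
    )
    mafs = ld.snp_mafs()
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    causal: list[int] = []
    for locus, maf in enumerate(scenario.causal_mafs):
        j = int(offsets[locus] + sizes[locus] // 2)
        causal.append(j)
        mafs[j] = maf
    ld = replace(ld, mafs=mafs)
    return ld, tuple(causal)


def simulate_genotypes(
    n_samples: int, ld: LdBlockModel, seed: int = 0
) -> np.ndarray:
    """Draw an (n_samples, n_snps) int8 dosage matrix from the block model."""
    rng = np.random.default_rng(derive_seed(ld.seed, 21, seed))
    mafs = ld.snp_mafs()
    thresholds = stats.norm.ppf(mafs)
    rho = ld.within_block_rho
    n_hap = 2 * n_samples
    dosage = np.empty((n_samples, ld.n_snps), dtype=np.int8)
    start = 0
    for b in ld.block_sizes:
        u = rng.standard_normal((n_hap, 1))
        e = rng.standard_normal((n_hap, b))
        z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
        hap = (z < thresholds[start : start + b]).astype(np.int8)
        dosage[:, start : start + b] = hap[0::2] + hap[1::2]
        start += b
    return dosage


def disease_model_for(
    scenario: ScenarioSpec,
    effects: EffectModelSpec,
    causal_indices: Sequence[int],
) -> DiseaseModel:
    """Assemble the DiseaseModel (solving the intercept) for a scenario."""
    betas = effects.betas()
    beta_extra = effects.beta_extra() if len(scenario.causal_mafs) == 4 else None
    alpha = solve_alpha(betas, scenario.causal_mafs, scenario.prevalence, beta_extra)
    return DiseaseModel(
        causal_snp_indices=tuple(causal_indices),
        causal_mafs=scenario.causal_mafs,
        alpha=alpha,
        beta=betas,
        prevalence=scenario.prevalence,
        beta_extra=beta_extra,
    )


def simulate_case_control(
    scenario: ScenarioSpec,
    effects: EffectModelSpec,
    ld: LdBlockModel | None = None,
    seed: int = 0,
    rho: float = DEFAULT_RHO,
    max_batches: int = 400,
) -> GenotypeMatrix:
    """Rejection-sample genotype rows until the case/control quotas are met.

    Each candidate individual's disease status is Bernoulli(penetrance(X))
    with X the dominant coding of its causal-locus genotypes; rows are kept
    until exactly ``n_cases`` cases and ``n_controls`` controls accumulate.
    """
    if ld is None:
        ld, causal = build_panel(scenario, rho=rho, seed=seed)
    else:
        _, causal = build_panel(scenario, rho=rho, seed=seed)
    model = disease_model_for(scenario, effects, causal)
    rng = np.random.default_rng(derive_seed(seed, 22))

    need_cases, need_controls = scenario.n_cases, scenario.n_controls
    # cases are the rare class at low prevalence; size batches for them
    batch = int(
        min(200_000, max(2048, 1.3 * need_cases / scenario.prevalence / 10))
    )
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    got_cases = got_controls = 0
    for b in range(max_batches):
        G = simulate_genotypes(batch, ld, seed=derive_seed(seed, 23, b))
        X = (G[:, list(causal)] > 0).astype(np.float64)
        prob = penetrance(X, model)
        is_case = rng.random(batch) < prob
        if got_cases < need_cases:
            take = G[is_case][: need_cases - got_cases]
            cases.append(take)
            got_cases += take.shape[0]
        if got_controls < need_controls:
            take = G[~is_case][: need_controls - got_controls]
            controls.append(take)
            got_controls += take.shape[0]
        if got_cases >= need_cases and got_controls >= need_controls:
            break
    else:
        raise RuntimeError(
            f"rejection sampling exhausted {max_batches} batches of {batch}: "
            f"got {got_cases}/{need_cases} cases, {got_controls}/{need_controls} "
            f"controls (prevalence {scenario.prevalence}, alpha {model.alpha:.3f})"
        )
    dosages = np.vstack([*cases, *controls])
    n = dosages.shape[0]
    phenotype = np.zeros(n, dtype=np.int8)
    phenotype[:need_cases] = 1
    return GenotypeMatrix(
        sample_ids=[f"case{i+1}" for i in range(need_cases)]
        + [f"ctrl{i+1}" for i in range(need_controls)],
        snp_ids=[f"snp{j+1:05d}" for j in range(scenario.n_snps)],
        dosages=dosages,
        phenotype=phenotype,
    )


@dataclass
class ExperimentResult:
    """Rejection-rate table, raw p-values and provenance of one experiment."""

    table: pd.DataFrame
    p_values: np.ndarray
    provenance: dict


def _rejection_table(pvals: np.ndarray, alpha_levels: Sequence[float]) -> pd.DataFrame:
    rows = []
    n = pvals.size
    for level in alpha_levels:
        k = int((pvals <= level).sum())
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        rows.append(
            {
                "level": level,
                "n_replicates": n,
                "n_rejections": k,
                "rejection_rate": k / n,
                "ci_low": ci.low,
                "ci_high": ci.high,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(
    scenario: ScenarioSpec,
    effects: EffectModelSpec,
    method: str,
    n_replicates: int,
    alpha_levels: Sequence[float] = (0.05, 0.01),
    K: int = 2000,
    seed: int = 0,
    forest: ForestConfig | None = None,
    rho: float = DEFAULT_RHO,
    importance_threshold: float | None = 1.64,
    progress: Callable[[int, float], None] | None = None,
) -> ExperimentResult:
    """Monte-Carlo rejection rates of one method under one scenario/model.

    Each replicate simulates a fresh case-control dataset, treats the whole
    simulated panel as the tested pathway, and records the method's
    permutation p-value; rates come with exact (Clopper-Pearson) 95% CIs.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if method not in ("trf", "rf", "setbased"):
        raise ValueError(f"unknown method {method!r}")
    forest = forest or ForestConfig()
    ld, _ = build_panel(scenario, rho=rho, seed=seed)
    pvals = np.empty(n_replicates)
    for rep in range(n_replicates):
        data_seed = derive_seed(seed, 30, rep)
        test_seed = derive_seed(seed, 31, rep)
        matrix = simulate_case_control(
            scenario, effects, ld=ld, seed=data_seed, rho=rho
        )
        snpset = PathwaySnpSet(
            pathway_id=scenario.name,
            snp_indices=tuple(range(matrix.n_snps)),
            n_genes_matched=scenario.n_genes,
        )
        if method == "setbased":
            res = set_based_test(
                matrix, snpset, SetTestConfig(n_permutations=K, seed=test_seed)
            )
        else:
            cfg = TrfConfig(
                importance_threshold=(
                    importance_threshold if method == "trf" else None
                ),
                n_permutations=K,
                forest=replace(forest, seed=test_seed),
            )
            run = trf_pathway_test if method == "trf" else rf_pathway_test
            res = run(matrix, snpset, cfg)
        pvals[rep] = res.p_value
        if progress is not None:
            progress(rep, res.p_value)
    provenance = {
        "scenario": scenario.name,
        "effects": effects.name,
        "method": method,
        "n_replicates": n_replicates,
        "K": K,
        "seed": seed,
        "rho": rho,
        "n_cases": scenario.n_cases,
        "n_controls": scenario.n_controls,
        "n_snps": scenario.n_snps,
        "n_genes": scenario.n_genes,
        "prevalence": scenario.prevalence,
        "n_trees": forest.n_trees,
        "importance_threshold": importance_threshold,
    }
    return ExperimentResult(
        table=_rejection_table(pvals, alpha_levels),
        p_values=pvals,
        provenance=provenance,
    )
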