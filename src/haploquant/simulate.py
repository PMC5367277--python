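"""Synthetic pedigrees and ordinal phenotypes with the study's structure.

The generator emulates a mark–recapture quantitative-genetic study of
*Polistes* paper wasps: single-foundress colonies whose daughters form
full-sibships (one wild-caught foundress plus one implicit haploid mate
per nest), a handful of known mother-of-foundress links across birth
cohorts, and ordinal colour scores produced by thresholding a Gaussian
liability composed of additive genetic, maternal, year and residual
components.

Defaults reproduce the study's sampling design: 83 nests over four birth
cohorts, ~9.3 phenotyped daughters per nest plus the phenotyped
foundress (~856 scored females in total), four cross-generation links,
and an additive liability proportion of 0.9 (V_A = 9 against the fixed
residual V_E = 1), the modal estimate for the facial colour traits.

A separate single-locus Mendelian mode (dominant presence allele,
heterozygous-or-recessive dam, haploid sire) calibrates the segregation
tests; it is never mixed with the polygenic generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .pedigree import (
    FEMALE,
    MALE,
    Individual,
    Pedigree,
    RelatednessMatrix,
    additive_matrix,
)

__all__ = [
    "SimulationConfig",
    "simulate_pedigree",
    "simulate_liabilities",
    "threshold_scores",
    "simulate_dataset",
    "simulate_single_locus",
    "random_pedigree",
]


@dataclass
class SimulationConfig:
    """Study design and liability-scale variance components.

    Variances are on the liability scale with the residual fixed at
    ``v_residual = 1`` by default, mirroring the identifiability
    constraint of ordinal threshold models, so requested and estimated
    components are directly comparable.  ``thresholds=None`` places the
    cut points at equal-frequency quantiles of the total liability
    distribution (every ordinal category equally likely).
    """

    n_nests: int = 83
    brood_mean: float = 9.3
    # negative-binomial size parameter (larger = tighter); None = every
    # nest gets exactly round(brood_mean) daughters
    brood_dispersion: float | None = 12.0
    brood_min: int = 1
    cohorts: tuple[str, ...] = ("2008", "2009", "2010", "2011")
    cross_generation_links: int = 4
    v_additive: float = 9.0
    v_maternal: float = 0.0
    v_year: float = 0.0
    v_residual: float = 1.0
    thresholds: tuple[float, ...] | None = None
    n_levels: int = 5
    trait_names: tuple[str, ...] = ("trait",)
    g_additive: np.ndarray | None = None  # trait x trait additive covariance
    phenotype_dams: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nests < 1:
            raise ValueError("n_nests must be >= 1")
        for name in ("v_additive", "v_maternal", "v_year", "v_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.thresholds is not None:
            tau = np.asarray(self.thresholds, dtype=float)
            if tau.ndim != 1 or np.any(np.diff(tau) <= 0):
                raise ValueError("thresholds must be strictly increasing")
        if self.g_additive is not None:
            g = np.asarray(self.g_additive, dtype=float)
            if g.shape != (len(self.trait_names), len(self.trait_names)):
                raise ValueError("g_additive shape must match trait_names")
            if not np.allclose(g, g.T):
                raise ValueError("g_additive must be symmetric")
            if np.linalg.eigvalsh(g)[0] < -1e-10:
                raise ValueError("g_additive must be positive semi-definite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def total_variance(self, trait: int = 0) -> float:
        if self.g_additive is not None:
            va = float(np.asarray(self.g_additive)[trait, trait])
        else:
            va = self.v_additive
        return va + self.v_maternal + self.v_year + self.v_residual

    def resolve_thresholds(self, trait: int = 0) -> np.ndarray:
        """Cut points; default = equal-frequency quantiles of the liability."""
        if self.thresholds is not None:
            return np.asarray(self.thresholds, dtype=float)
        from scipy.stats import norm

        sd = np.sqrt(self.total_variance(trait))
        probs = np.arange(1, self.n_levels) / self.n_levels
        return sd * norm.ppf(probs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["g_additive"] is not None:
            out["g_additive"] = np.asarray(out["g_additive"]).tolist()
        return out


def _truncated_negbinom(rng: np.random.Generator, cfg: SimulationConfig, size: int):
    """Brood sizes: negative binomial (mean, dispersion), truncated at min."""
    k = cfg.brood_dispersion
    if k is None:
        return np.full(size, max(int(round(cfg.brood_mean)), cfg.brood_min), dtype=np.int64)
    p = k / (k + cfg.brood_mean)
    draws = np.empty(size, dtype=np.int64)
    filled = 0
    while filled < size:
        batch = rng.negative_binomial(k, p, size=size - filled)
        keep = batch[batch >= cfg.brood_min]
        draws[filled : filled + keep.size] = keep
        filled += keep.size
    return draws


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Single-foundress nests with one dummy haploid sire each.

    Nests are allocated to cohorts round-robin.  ``cross_generation_links``
    nests in cohorts after the first have a foundress drawn from the
    daughters of a previous-cohort nest, mirroring the known
    mother-of-foundress links; all other foundresses are founders of
    unknown ancestry (their own birth cohort is the season before their
    nest's cohort).
    """
    rng = np.random.default_rng(cfg.seed)
    cohort_of_nest = [cfg.cohorts[i % len(cfg.cohorts)] for i in range(cfg.n_nests)]
    # Build in cohort order so linked foundresses already exist.
    nest_order = sorted(range(cfg.n_nests), key=lambda i: (cfg.cohorts.index(cohort_of_nest[i]), i))

    eligible_for_link = [
        i for i in nest_order if cfg.cohorts.index(cohort_of_nest[i]) > 0
    ]
    if cfg.cross_generation_links > len(eligible_for_link):
        raise ValueError(
            f"cannot place {cfg.cross_generation_links} cross-generation links: "
            f"only {len(eligible_for_link)} nests are in later cohorts"
        )
    linked = set(
        rng.choice(eligible_for_link, size=cfg.cross_generation_links, replace=False)
        if cfg.cross_generation_links
        else []
    )

    broods = _truncated_negbinom(rng, cfg, cfg.n_nests)
    individuals: list[Individual] = []
    daughters_by_cohort: dict[str, list[str]] = {c: [] for c in cfg.cohorts}
    used_as_dam: set[str] = set()

    def _prior_cohort(c: str) -> str:
        k = cfg.cohorts.index(c)
        if k > 0:
            return cfg.cohorts[k - 1]
        try:
            return str(int(c) - 1)
        except ValueError:
            return f"pre-{c}"

    for i in nest_order:
        cohort = cohort_of_nest[i]
        nest = f"n{cohort}.{i:03d}"
        if i in linked:
            pool = [
                d
                for d in daughters_by_cohort[_prior_cohort(cohort)]
                if d not in used_as_dam
            ]
            if not pool:
                raise ValueError(
                    f"no prior-cohort daughters available to found nest {nest}"
                )
            dam_id = str(rng.choice(pool))
            used_as_dam.add(dam_id)
        else:
            dam_id = f"F.{nest}"
            individuals.append(
                Individual(
                    id=dam_id, sex=FEMALE, nest=nest, cohort=_prior_cohort(cohort)
                )
            )
        sire_id = f"S.{nest}"
        individuals.append(Individual(id=sire_id, sex=MALE, nest=nest))
        for j in range(broods[i]):
            did = f"{nest}.d{j:02d}"
            individuals.append(
                Individual(
                    id=did, sex=FEMALE, dam=dam_id, sire=sire_id, nest=nest,
                    cohort=cohort,
                )
            )
            daughters_by_cohort[cohort].append(did)
    return Pedigree(individuals)


def _block_cholesky_sample(
    s: np.ndarray, rng: np.random.Generator, n_traits: int
) -> np.ndarray:
    """Draw Z with cov(vec Z) = I_t (x) S, exploiting S's block structure.

    Pedigrees of near-independent full-sib nests make S block diagonal up
    to the few cross-generation links; sampling per connected component
    keeps the cost linear in the number of individuals.
    """
    n = s.shape[0]
    out = np.zeros((n, n_traits))
    n_comp, labels = connected_components(csr_matrix(s != 0.0), directed=False)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        block = s[np.ix_(idx, idx)]
        chol = np.linalg.cholesky(block + 1e-10 * np.eye(idx.size))
        out[idx] = chol @ rng.standard_normal((idx.size, n_traits))
    return out


def simulate_liabilities(
    ped: Pedigree,
    cfg: SimulationConfig,
    s_matrix: RelatednessMatrix | None = None,
) -> pd.DataFrame:
    """Gaussian liabilities l = a + m_dam + y_cohort + e for phenotyped females.

    Additive values follow N(0, V_A * S) (multivariate: cov G (x) S via
    per-block Cholesky factors); maternal deviations are drawn per dam
    (foundresses of unknown mother get a unique maternal level), year
    deviations per birth-cohort label, residuals independently.
    Returns a long table (id, trait, liability).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    subset = _phenotyped_females(ped, cfg)
    if s_matrix is None:
        s_matrix = additive_matrix(ped, subset)
    elif tuple(s_matrix.ids) != tuple(subset):
        s_matrix = s_matrix.submatrix(subset)
    n = len(subset)
    t = cfg.n_traits

    if cfg.g_additive is not None:
        g = np.asarray(cfg.g_additive, dtype=float)
    else:
        g = np.array([[cfg.v_additive]])
        if t != 1:
            raise ValueError("multi-trait simulation requires g_additive")
    eigval = np.linalg.eigvalsh(g)
    if eigval[0] < -1e-10:
        raise ValueError("requested additive covariance is not PSD")
    # Matrix square root of G; Cholesky when PD, eigen fallback at the boundary.
    try:
        g_half = np.linalg.cholesky(g)
    except np.linalg.LinAlgError:
        d, u = np.linalg.eigh(g)
        g_half = u @ np.diag(np.sqrt(np.maximum(d, 0.0)))

    z = _block_cholesky_sample(s_matrix.values, rng, t)
    additive = z @ g_half.T  # rows: individuals, cols: traits

    dams = [ped[i].dam for i in subset]
    dam_levels = sorted({d for d in dams if d is not None})
    dam_effect = {d: rng.normal(0.0, np.sqrt(cfg.v_maternal), size=t) for d in dam_levels}
    maternal = np.array(
        [
            dam_effect[d] if d is not None
            else rng.normal(0.0, np.sqrt(cfg.v_maternal), size=t)
            for d in dams
        ]
    )

    cohorts = [ped[i].cohort for i in subset]
    cohort_levels = sorted({c for c in cohorts if c is not None})
    year_effect = {c: rng.normal(0.0, np.sqrt(cfg.v_year), size=t) for c in cohort_levels}
    year = np.array(
        [
            year_effect[c] if c is not None
            else rng.normal(0.0, np.sqrt(cfg.v_year), size=t)
            for c in cohorts
        ]
    )

    resid = rng.normal(0.0, np.sqrt(cfg.v_residual), size=(n, t))
    liab = additive + maternal + year + resid

    records = []
    for j, trait in enumerate(cfg.trait_names):
        for i, id_ in enumerate(subset):
            records.append((id_, trait, liab[i, j], additive[i, j]))
    return pd.DataFrame(records, columns=["id", "trait", "liability", "additive"])


def threshold_scores(liabilities, thresholds) -> np.ndarray:
    """Ordinal score = number of thresholds strictly below the liability."""
    tau = np.asarray(thresholds, dtype=float)
    if tau.ndim != 1 or np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.searchsorted(tau, np.asarray(liabilities, dtype=float), side="left")


def simulate_dataset(cfg: SimulationConfig):
    """Pedigree + phenotype table + truth sidecar, in one call.

    Returns ``(ped, phenotypes, truth)`` where phenotypes is a long table
    (id, trait, score, liability) and truth echoes the configuration,
    resolved thresholds and seed for downstream parameter-recovery checks.
    """
    ped = simulate_pedigree(cfg)
    liab = simulate_liabilities(ped, cfg)
    frames = []
    thresholds = {}
    for j, trait in enumerate(cfg.trait_names):
        tau = cfg.resolve_thresholds(j)
        thresholds[trait] = tau.tolist()
        sub = liab[liab["trait"] == trait].copy()
        sub["score"] = threshold_scores(sub["liability"].to_numpy(), tau)
        frames.append(sub)
    phen = pd.concat(frames, ignore_index=True)[
        ["id", "trait", "score", "liability"]
    ]
    truth = {
        "config": cfg.to_dict(),
        "thresholds": thresholds,
        "seed": cfg.seed,
    }
    return ped, phen, truth


def _phenotyped_females(ped: Pedigree, cfg: SimulationConfig) -> tuple[str, ...]:
    if cfg.phenotype_dams:
        return ped.females
    dams = {ind.dam for ind in ped if ind.dam is not None}
    return tuple(i for i in ped.females if ped[i].dam is not None or i not in dams)


def simulate_single_locus(
    ped: Pedigree,
    seed: int = 0,
    p_dam_heterozygous: float = 0.5,
    p_sire_dominant: float = 0.5,
    trait: str = "presence",
):
    """Single-locus dominant presence trait under haplodiploid Mendelism.

    Founder dams are heterozygous (Aa) with probability
    ``p_dam_heterozygous`` and otherwise homozygous recessive (aa);
    haploid founder sires carry the dominant allele with probability
    ``p_sire_dominant``.  Daughters inherit one random maternal allele
    plus the paternal allele; presence means carrying at least one
    dominant allele.  With a heterozygous dam and a recessive sire,
    exactly half the daughters are expected to show the trait — the
    Mendelian 50:50 null of the segregation tests.

    Returns ``(phenotypes, genotypes)``: a (id, trait, score) table with
    scores in {0, 1} for every female, and the underlying allele table.
    """
    rng = np.random.default_rng(seed)
    alleles: dict[str, np.ndarray] = {}
    for ind in ped:
        d, s = ind.dam, ind.sire
        if ind.sex == FEMALE:
            if d is None and s is None:
                het = rng.random() < p_dam_heterozygous
                geno = np.array([1, 0]) if het else np.array([0, 0])
            else:
                maternal = (
                    alleles[d][rng.integers(0, 2)] if d is not None else 0
                )
                paternal = alleles[s][0] if s is not None else 0
                geno = np.array([maternal, paternal])
        else:
            if d is None:
                a = int(rng.random() < p_sire_dominant)
            else:
                a = int(alleles[d][rng.integers(0, 2)])
            geno = np.array([a, a])
        alleles[ind.id] = geno

    records = [
        (i, trait, int(alleles[i].max() > 0)) for i in ped.females
    ]
    phen = pd.DataFrame(records, columns=["id", "trait", "score"])
    geno = pd.DataFrame(
        [(i, int(alleles[i][0]), int(alleles[i][1])) for i in ped.ids],
        columns=["id", "allele1", "allele2"],
    )
    return phen, geno


def random_pedigree(seed: int, n: int = 30, p_has_parents: float = 0.7) -> Pedigree:
    """Random valid pedigree for property testing.

    Individuals are created in topological order; each non-founder picks
    a dam among earlier females and a sire among earlier males (either
    side may independently be missing).
    """
    rng = np.random.default_rng(seed)
    individuals: list[Individual] = []
    females: list[str] = []
    males: list[str] = []
    for i in range(n):
        sex = FEMALE if rng.random() < 0.6 else MALE
        dam = sire = None
        if rng.random() < p_has_parents:
            if females and rng.random() < 0.9:
                dam = str(rng.choice(females))
            if sex == FEMALE and males and rng.random() < 0.9:
                sire = str(rng.choice(males))
        id_ = f"i{i:03d}"
        individuals.append(Individual(id=id_, sex=sex, dam=dam, sire=sire))
        (females if sex == FEMALE else males).append(id_)
    return Pedigree(individuals)
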