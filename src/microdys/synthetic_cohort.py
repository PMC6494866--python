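"""Synthetic two-group duodenal-aspirate cohort generator.

Emulates the statistical structure the downstream analyses assume: a
reference (healthy) group and a larger symptomatic group, genus-level
profiles with a geometric rank-abundance curve and Dirichlet-multinomial
overdispersion, a dysbiotic case subpopulation produced by depleting a set
of moderately abundant genera, clinical covariates with stated prevalences
optionally linked to the latent dysbiotic class, log-normal sequencing
depths with a configurable fraction of shallow (< 1000 read) samples, and a
random phylogeny over the genera.

Ground truth (per-sample latent class, per-taxon fold changes) is recorded
so recovery by the dysbiosis and differential-abundance modules can be
measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from microdys.tables_io import CountTable, RANKS

__all__ = [
    "CovariateModel",
    "CohortSpec",
    "SyntheticCohort",
    "geometric_rank_abundance",
    "simulate_dirichlet_multinomial",
    "inject_differential_effect",
    "simulate_covariates",
    "simulate_tree",
    "generate_cohort",
]


@dataclass
class CovariateModel:
    """Prevalences and class-linkage for the clinical covariates.

    ``odds_multipliers`` map covariate name -> multiplicative change in the
    odds of the covariate being present for dysbiotic-class samples (1.0 =
    independent of class).  Age is drawn uniformly on ``age_range`` for a
    class-independent baseline and shifted up by ``age_shift_dysbiotic``
    years for dysbiotic samples (older age associates with dysbiosis).
    """

    prevalence: dict = field(
        default_factory=lambda: {
            "antibiotics_recent": 0.20,
            "ppi": 0.35,
            "gi_surgery": 0.214,
            "sex_male": 0.25,
        }
    )
    odds_multipliers: dict = field(
        default_factory=lambda: {
            "antibiotics_recent": 2.5,
            "ppi": 2.0,
            "gi_surgery": 2.0,
            "sex_male": 1.0,
        }
    )
    age_range: tuple = (18.0, 89.0)
    age_shift_dysbiotic: float = 8.0
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    sibo_prevalence: float = 0.52


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 38 reference (healthy) and
    126 case (symptomatic) samples over 65 genera; geometric rank-abundance
    decay 0.85; Dirichlet overdispersion theta = 0.02; log-normal depths
    with median 20k reads and sigma 0.5 log units plus a 5% fraction forced
    below 1000 reads; 30% of cases drawn from a dysbiotic distribution in
    which 26 moderately abundant genera (abundance ranks 6-31) are depleted
    to 10% of their baseline mean.
    """

    n_reference: int = 38
    n_case: int = 126
    n_taxa: int = 65
    base_decay: float = 0.85
    dispersion: float = 0.02
    depth_log_median: float = 20000.0
    depth_log_sigma: float = 0.5
    low_depth_fraction: float = 0.05
    differential_taxa: tuple = tuple(range(5, 31))  # 0-based: abundance ranks 6-31
    fold_changes: float | tuple = 0.1
    dysbiotic_fraction: float = 0.3
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dysbiotic_fraction <= 1:
            raise ValueError("dysbiotic_fraction must be in [0, 1]")
        if not 0 <= self.low_depth_fraction <= 1:
            raise ValueError("low_depth_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion theta must be > 0")
        if not 0 < self.base_decay < 1:
            raise ValueError("base_decay must be in (0, 1)")
        folds = np.atleast_1d(np.asarray(self.fold_changes, dtype=float))
        if (folds <= 0).any():
            raise ValueError("fold changes must be > 0")
        if folds.size == 1:
            # scalar fold: restrict the default target set to existing taxa
            kept = tuple(i for i in self.differential_taxa if 0 <= i < self.n_taxa)
            object.__setattr__(self, "differential_taxa", kept)


@dataclass
class SyntheticCohort:
    """A generated cohort: counts, metadata, tree, and ground truth."""

    table: CountTable
    metadata: pd.DataFrame
    tree: TreeNode
    truth: pd.DataFrame          # per sample: group, latent_class
    taxon_truth: pd.DataFrame    # per taxon: dysbiotic-class fold change


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive independent child generators from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def geometric_rank_abundance(n_taxa: int, decay: float) -> np.ndarray:
    """Mean proportions decaying geometrically with abundance rank."""
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    p = decay ** np.arange(n_taxa)
    return p / p.sum()


def simulate_dirichlet_multinomial(
    mean_proportions: np.ndarray,
    dispersion: float,
    depth,
    n: int,
    seed=None,
) -> np.ndarray:
    """Draw ``n`` samples from a Dirichlet-multinomial model.

    Each sample's composition is Dirichlet with concentration
    ``mean_proportions / dispersion`` (so the Dirichlet mean equals
    ``mean_proportions`` and total concentration 1/theta controls
    overdispersion), then counts are multinomial at the requested depth.

    Parameters
    ----------
    depth : int or array of int
        Per-sample read depth (scalar broadcast to all samples).
    seed : int, Generator, or None

    Returns
    -------
    counts : int array, shape (n_taxa, n)
        Column sums equal the requested depths.
    """
    p = np.asarray(mean_proportions, dtype=float)
    if p.size == 0:
        raise ValueError("mean_proportions must be non-empty")
    if p.ndim != 1 or (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("mean_proportions must be a simplex vector")
    if dispersion <= 0:
        raise ValueError("dispersion theta must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    depths = np.broadcast_to(np.asarray(depth, dtype=np.int64), (n,))
    alpha = p / dispersion
    # Gamma-based Dirichlet draw tolerates alpha_i == 0 (taxon never present).
    gam = rng.gamma(np.broadcast_to(alpha, (n, p.size)))
    rowsum = gam.sum(axis=1, keepdims=True)
    comps = np.where(rowsum > 0, gam / np.where(rowsum == 0, 1, rowsum), 0)
    counts = rng.multinomial(depths, comps)
    return counts.T  # taxa x samples


def inject_differential_effect(
    mean_proportions: np.ndarray,
    differential_taxa,
    fold_changes,
) -> np.ndarray:
    """Multiply targeted mean proportions by fold changes and renormalize."""
    p = np.asarray(mean_proportions, dtype=float).copy()
    idx = np.asarray(list(differential_taxa), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= p.size):
        raise IndexError("differential taxon index out of range")
    folds = np.broadcast_to(np.asarray(fold_changes, dtype=float), idx.shape)
    if (folds <= 0).any():
        raise ValueError("fold changes must be > 0")
    p[idx] *= folds
    return p / p.sum()


def simulate_covariates(
    n: int,
    covariate_model: CovariateModel | None = None,
    seed=None,
    latent_class=None,
    group: str = "symptomatic",
) -> pd.DataFrame:
    """Draw per-sample clinical covariates.

    Binary covariates are Bernoulli at the model prevalences; for samples
    flagged dysbiotic in ``latent_class`` the odds are multiplied by the
    model's odds multipliers.  Age is uniform on the model range (plus the
    dysbiotic age shift); BMI is normal.  SIBO culture CFU/mL is drawn
    log-uniform on either side of the 1e5 threshold according to the SIBO
    prevalence (cases only; reference samples are culture-negative).
    """
    model = covariate_model or CovariateModel()
    for name, prev in model.prevalence.items():
        if not 0 <= prev <= 1:
            raise ValueError(f"prevalence for {name!r} must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dys = np.zeros(n, dtype=bool) if latent_class is None else np.asarray(latent_class, dtype=bool)

    cols: dict[str, np.ndarray] = {}
    for name, prev in model.prevalence.items():
        mult = model.odds_multipliers.get(name, 1.0)
        if prev in (0.0, 1.0):
            prob = np.full(n, prev)
        else:
            odds = prev / (1 - prev) * np.where(dys, mult, 1.0)
            prob = odds / (1 + odds)
        cols[name] = rng.random(n) < prob

    lo, hi = model.age_range
    age = rng.uniform(lo, hi, size=n) + np.where(dys, model.age_shift_dysbiotic, 0.0)
    age = np.clip(age, lo, hi)
    bmi = rng.normal(model.bmi_mean, model.bmi_sd, size=n).clip(15, 60)

    if group == "symptomatic":
        sibo_pos = rng.random(n) < model.sibo_prevalence
        cfu = np.where(
            sibo_pos,
            10 ** rng.uniform(5.0, 8.0, size=n),
            10 ** rng.uniform(1.0, 5.0, size=n) * (1 - 1e-9),
        )
    else:
        cfu = 10 ** rng.uniform(1.0, 5.0, size=n) * (1 - 1e-9)

    absent = np.zeros(n, dtype=bool)  # covariates without a stated prevalence
    meta = pd.DataFrame(
        {
            "group": group,
            "age": np.round(age, 1),
            "sex": np.where(cols.pop("sex_male", absent), "M", "F"),
            "bmi": np.round(bmi, 1),
            "antibiotics_recent": cols.get("antibiotics_recent", absent),
            "ppi": cols.get("ppi", absent),
            "gi_surgery": cols.get("gi_surgery", absent),
            "sibo_cfu": cfu,
            "indication": "synthetic",
        }
    )
    return meta


def simulate_tree(taxon_ids, seed=None) -> TreeNode:
    """Random bifurcating rooted tree with exponential branch lengths."""
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nodes = []
    for name in taxon_ids:
        tip = TreeNode(name=name)
        tip.length = float(rng.exponential(1.0))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`CohortSpec`.

    Reference samples come from the base rank-abundance distribution; a
    ``dysbiotic_fraction`` of cases come from the depletion-shifted
    distribution.  Ground truth for every sample and taxon is recorded.
    """
    spec = spec or CohortSpec()
    (rng_ref, rng_case, rng_depth, rng_cov_ref, rng_cov_case, rng_tree, rng_class) = _child_rngs(
        spec.seed, 7
    )

    base = geometric_rank_abundance(spec.n_taxa, spec.base_decay)
    shifted = inject_differential_effect(base, spec.differential_taxa, spec.fold_changes)

    n_total = spec.n_reference + spec.n_case
    depths = np.round(
        np.exp(rng_depth.normal(np.log(spec.depth_log_median), spec.depth_log_sigma, n_total))
    ).astype(np.int64)
    shallow = rng_depth.random(n_total) < spec.low_depth_fraction
    depths[shallow] = rng_depth.integers(100, 1000, size=int(shallow.sum()))

    dys = rng_class.random(spec.n_case) < spec.dysbiotic_fraction

    ref_counts = simulate_dirichlet_multinomial(
        base, spec.dispersion, depths[: spec.n_reference], spec.n_reference, rng_ref
    )
    case_counts = np.empty((spec.n_taxa, spec.n_case), dtype=np.int64)
    case_depths = depths[spec.n_reference :]
    healthy_like = ~dys
    if healthy_like.any():
        case_counts[:, healthy_like] = simulate_dirichlet_multinomial(
            base, spec.dispersion, case_depths[healthy_like], int(healthy_like.sum()), rng_case
        )
    if dys.any():
        case_counts[:, dys] = simulate_dirichlet_multinomial(
            shifted, spec.dispersion, case_depths[dys], int(dys.sum()), rng_case
        )

    taxon_ids = [f"g{i + 1:03d}" for i in range(spec.n_taxa)]
    sample_ids = [f"H{i + 1:03d}" for i in range(spec.n_reference)] + [
        f"S{i + 1:03d}" for i in range(spec.n_case)
    ]
    counts = pd.DataFrame(
        np.hstack([ref_counts, case_counts]), index=taxon_ids, columns=sample_ids
    )
    # Single-kingdom genus-level taxonomy spread over a few synthetic phyla.
    phylum = [f"p{(i % 4) + 1}" for i in range(spec.n_taxa)]
    taxonomy = pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": phylum,
            "class": [f"c{(i % 8) + 1}" for i in range(spec.n_taxa)],
            "order": [f"o{(i % 12) + 1}" for i in range(spec.n_taxa)],
            "family": [f"f{(i % 20) + 1}" for i in range(spec.n_taxa)],
            "genus": taxon_ids,
        },
        index=taxon_ids,
        columns=list(RANKS[:6]),
    )
    table = CountTable(counts, taxonomy)

    meta_ref = simulate_covariates(
        spec.n_reference, spec.covariate_model, rng_cov_ref, latent_class=None, group="healthy"
    )
    meta_case = simulate_covariates(
        spec.n_case, spec.covariate_model, rng_cov_case, latent_class=dys, group="symptomatic"
    )
    metadata = pd.concat([meta_ref, meta_case], ignore_index=True)
    metadata.index = pd.Index(sample_ids, name="#SampleID")

    tree = simulate_tree(taxon_ids, rng_tree)

    truth = pd.DataFrame(
        {
            "group": metadata["group"],
            "latent_class": ["healthy-like"] * spec.n_reference
            + ["dysbiotic" if d else "healthy-like" for d in dys],
        },
        index=metadata.index,
    )
    folds = np.ones(spec.n_taxa)
    idx = np.asarray(list(spec.differential_taxa), dtype=int)
    folds[idx] = np.broadcast_to(np.asarray(spec.fold_changes, dtype=float), idx.shape)
    taxon_truth = pd.DataFrame(
        {"fold_change_dysbiotic": folds}, index=pd.Index(taxon_ids, name="#TaxonID")
    )
    return SyntheticCohort(table, metadata, tree, truth, taxon_truth)
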