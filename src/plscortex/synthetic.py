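"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline — w-scoring, case-control contrasts,
PLS1 gene association, receptor mapping, and pathology-set overlap — needs a
region x gene expression matrix, a subject-level cortical thickness cohort,
a receptor-density atlas, and pathology gene lists. The study cohort behind
the original analysis is private, so this module generates all four with
known planted structure:

* the expression matrix is low-rank with smooth spatial factors, and a block
  of "planted" genes loads predominantly on factor 1;
* patient thickness cohorts carry a group atrophy pattern proportional to
  that same factor, so the case-control contrast map is transcriptomically
  decodable by construction;
* receptor maps are noisy mixtures with prescribed expected correlation to
  the atrophy map;
* pathology gene lists contain a prescribed fraction of the planted genes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SyntheticTruth",
    "ReceptorAtlas",
    "DEFAULT_RECEPTORS",
    "make_expression",
    "make_cohort",
    "make_receptor_atlas",
    "make_pathology_sets",
]

#: 15 receptors/transporters spanning five neurotransmitter systems, the
#: standard PET-derived set used in regional receptor-density atlases.
DEFAULT_RECEPTORS: dict[str, str] = {
    "5HT1A": "serotonin",
    "5HT1B": "serotonin",
    "5HT2A": "serotonin",
    "5HT4": "serotonin",
    "5HTT": "serotonin",
    "D1": "dopamine",
    "D2": "dopamine",
    "DAT": "dopamine",
    "GABAa": "GABA",
    "mGluR5": "glutamate",
    "NMDA": "glutamate",
    "5HT6": "serotonin",
    "M1": "acetylcholine",
    "A4B2": "acetylcholine",
    "VAChT": "acetylcholine",
}

#: Subject metadata columns; every other column of a cohort table is a region.
SUBJECT_META_COLUMNS = ["subject_id", "group", "age", "sex", "duration"]


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic dataset, for recovery checks.

    Attributes
    ----------
    planted_gene_ids
        Genes whose expression loads predominantly on the atrophy-linked
        spatial factor (factor 1).
    planted_effect
        Group atrophy effect size in w-score units (set by :func:`make_cohort`).
    receptor_target_correlations
        Intended Pearson correlation of each synthetic receptor map with the
        noiseless atrophy map, each in [-1, 1].
    planted_overlap_fraction
        Fraction of signature genes inserted into a synthetic pathology list.
    seed
        Seed of the generator call that produced the artefact.
    spatial_factors
        region x latent matrix of the smooth factors underlying the
        expression matrix; column ``factor_1`` is the atrophy-linked one.
    """

    planted_gene_ids: list[str] = field(default_factory=list)
    planted_effect: float = 0.0
    receptor_target_correlations: list[float] = field(default_factory=list)
    planted_overlap_fraction: float = 0.0
    seed: int = 0
    spatial_factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for r in self.receptor_target_correlations:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"target correlation {r} outside [-1, 1]")
        if not 0.0 <= self.planted_overlap_fraction <= 1.0:
            raise ValueError("planted_overlap_fraction must lie in [0, 1]")


@dataclass
class ReceptorAtlas:
    """Region x receptor density table with neurotransmitter-system labels."""

    densities: pd.DataFrame
    systems: dict[str, str]

    def __post_init__(self) -> None:
        if self.densities.shape[1] < 1:
            raise ValueError("atlas needs at least one receptor")
        if self.densities.columns.duplicated().any():
            dup = self.densities.columns[self.densities.columns.duplicated()][0]
            raise ValueError(f"duplicate receptor name: {dup}")
        if self.densities.isna().any().any():
            raise ValueError("atlas contains missing values")

    @property
    def receptors(self) -> list[str]:
        return list(self.densities.columns)

    def to_tsv(self, path) -> None:
        """Write densities with a leading metadata row mapping receptor -> system."""
        meta = pd.DataFrame(
            [[self.systems.get(r, "unknown") for r in self.densities.columns]],
            index=["__system__"], columns=self.densities.columns,
        )
        pd.concat([meta, self.densities.astype(object)]).to_csv(
            path, sep="\t", index_label="region"
        )

    @classmethod
    def from_tsv(cls, path) -> "ReceptorAtlas":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        systems = raw.loc["__system__"].to_dict()
        dens = raw.drop(index="__system__").astype(float)
        return cls(densities=dens, systems=systems)


def _region_labels(n: int) -> list[str]:
    return [f"LH_region_{i + 1:03d}" for i in range(n)]


def _smooth_factors(n_regions: int, n_latent: int, rng: np.random.Generator) -> np.ndarray:
    """Low-order smooth spatial factors over a 1-D anterior-posterior ordering.

    Each factor is a sinusoid of increasing order plus smoothed noise, then
    standardized — a stand-in for the smooth expression gradients real
    cortical maps show, without needing surface geometry.
    """
    t = np.linspace(0.0, 1.0, n_regions)
    sigma = max(n_regions / 10.0, 1.0)
    cols = []
    for k in range(n_latent):
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin((k + 1) * np.pi * t + phase)
        rough = gaussian_filter1d(rng.standard_normal(n_regions), sigma=sigma)
        f = wave + 0.8 * rough
        f = (f - f.mean()) / f.std()
        cols.append(f)
    return np.column_stack(cols)


def make_expression(
    n_regions: int = 100,
    n_genes: int = 2000,
    n_latent: int = 3,
    noise_sd: float = 0.5,
    n_planted: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a low-rank, spatially structured region x gene matrix.

    X = S G^T + noise, where S (n_regions x n_latent) holds smooth spatial
    factors and G (n_genes x n_latent) gene loadings. The first ``n_planted``
    genes (before column shuffling) load predominantly on factor 1; the truth
    object records their identifiers and the factors themselves.

    Returns the matrix as a DataFrame (regions as rows, genes as columns)
    plus the :class:`SyntheticTruth`.
    """
    if n_regions <= 0 or n_genes <= 0 or n_latent <= 0:
        raise ValueError("n_regions, n_genes and n_latent must be positive")
    if n_planted is None:
        n_planted = max(1, n_genes // 10)  # a tenth of the universe by default
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    if n_regions < n_latent:
        raise ValueError("need at least as many regions as latent factors")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    S = _smooth_factors(n_regions, n_latent, rng)

    G = rng.normal(0.0, 0.3, size=(n_genes, n_latent))
    if n_planted:
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        G[:n_planted, 0] = signs * rng.normal(2.0, 0.25, size=n_planted)
    if n_latent > 1:
        # non-planted genes draw the bulk of their loading off factor 1
        G[n_planted:, 1:] = rng.normal(0.0, 1.0, size=(n_genes - n_planted, n_latent - 1))

    X = S @ G.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)

    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    planted = [str(g) for g in genes[:n_planted]]
    order = rng.permutation(n_genes)

    regions = _region_labels(n_regions)
    df = pd.DataFrame(X[:, order], index=regions, columns=genes[order])
    df.index.name = "region"

    factors = pd.DataFrame(
        S, index=regions, columns=[f"factor_{k + 1}" for k in range(n_latent)]
    )
    truth = SyntheticTruth(
        planted_gene_ids=planted, seed=seed, spatial_factors=factors
    )
    return df, truth


def make_cohort(
    n_controls: int = 172,
    n_sporadic: int = 117,
    n_genetic: int = 32,
    atrophy_map: pd.Series | np.ndarray | None = None,
    effect: float = 1.5,
    seed: int = 0,
    genetic_label: str = "genetic",
    n_regions: int | None = None,
) -> pd.DataFrame:
    """Generate a per-subject regional cortical-thickness table.

    One row per subject with columns ``subject_id, group, age, sex, duration``
    followed by one thickness column per region (mm). Controls follow a
    baseline + age/sex model with Gaussian residual noise; the genetic group
    is additionally shifted by ``effect`` (w-score units) times the
    standardized ``atrophy_map``; the sporadic group by ``effect/3`` times a
    distinct smooth map, so the genetic-vs-sporadic contrast is dominated by
    the planted pattern and ``effect=0`` makes all patient groups
    exchangeable with controls.

    Demographics mirror a typical neurodegeneration cohort: age uniform on
    45-75 years, sex Bernoulli(0.5), disease duration Gamma with mean 3.8
    and SD 2.7 years (controls have no duration).
    """
    if n_controls < 10:
        raise ValueError("need at least 10 controls to fit a w-score model")
    rng = np.random.default_rng(seed)

    if atrophy_map is None:
        if n_regions is None:
            raise ValueError("provide atrophy_map or n_regions")
        amap = np.zeros(n_regions)
        regions = _region_labels(n_regions)
    elif isinstance(atrophy_map, pd.Series):
        amap = atrophy_map.to_numpy(dtype=float)
        regions = list(atrophy_map.index)
    else:
        amap = np.asarray(atrophy_map, dtype=float)
        regions = _region_labels(amap.size)
    n_reg = amap.size
    if n_regions is not None and n_regions != n_reg:
        raise ValueError(
            f"atrophy_map has {n_reg} regions but n_regions={n_regions}"
        )

    sd = amap.std()
    amap_z = (amap - amap.mean()) / sd if sd > 0 else np.zeros_like(amap)

    # a distinct smooth map for the sporadic group's own atrophy pattern
    other = _smooth_factors(n_reg, 1, rng)[:, 0]

    baseline = 2.5 + 0.3 * _smooth_factors(n_reg, 1, rng)[:, 0]
    age_coef, sex_coef, resid_sd = -0.010, 0.05, 0.10  # mm/yr, mm, mm

    groups = (
        ["control"] * n_controls
        + ["sporadic"] * n_sporadic
        + [genetic_label] * n_genetic
    )
    n_total = len(groups)
    age = rng.uniform(45.0, 75.0, size=n_total)
    sex = rng.integers(0, 2, size=n_total).astype(float)
    # Gamma(shape, scale) with mean 3.8 y, sd 2.7 y
    shape = (3.8 / 2.7) ** 2
    duration = rng.gamma(shape, 3.8 / shape, size=n_total)
    duration[: n_controls] = np.nan

    shift = np.zeros((n_total, n_reg))
    is_gen = np.array([g == genetic_label for g in groups])
    is_spo = np.array([g == "sporadic" for g in groups])
    shift[is_gen] = effect * resid_sd * amap_z
    shift[is_spo] = (effect / 3.0) * resid_sd * other

    thick = (
        baseline[None, :]
        + age_coef * (age[:, None] - 60.0)
        + sex_coef * sex[:, None]
        + shift
        + rng.normal(0.0, resid_sd, size=(n_total, n_reg))
    )

    meta = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n_total)],
            "group": groups,
            "age": age,
            "sex": sex,
            "duration": duration,
        }
    )
    return pd.concat([meta, pd.DataFrame(thick, columns=regions)], axis=1)


def make_receptor_atlas(
    atrophy_map: pd.Series,
    target_correlations: list[float] | np.ndarray | None = None,
    seed: int = 0,
    receptor_names: list[str] | None = None,
) -> tuple[ReceptorAtlas, SyntheticTruth]:
    """Generate receptor-density maps with prescribed expected correlations.

    Each receptor column is ``r * z(atrophy) + sqrt(1 - r^2) * z(noise)``
    (z = standardization), so its expected Pearson correlation with the
    atrophy map equals the target ``r``. Columns are then given plausible
    density scales; correlation is affine-invariant so targets are preserved.
    """
    if target_correlations is None:
        target_correlations = [0.0] * len(DEFAULT_RECEPTORS)
    targets = np.asarray(target_correlations, dtype=float)
    if np.any(np.abs(targets) >= 1.0):
        raise ValueError("target correlations must lie strictly inside (-1, 1)")

    if receptor_names is None:
        names = list(DEFAULT_RECEPTORS)[: targets.size]
        if len(names) < targets.size:
            names += [f"receptor_{i + 1}" for i in range(len(names), targets.size)]
        systems = {n: DEFAULT_RECEPTORS.get(n, "unknown") for n in names}
    else:
        names = list(receptor_names)
        systems = {n: DEFAULT_RECEPTORS.get(n, "unknown") for n in names}
    if len(names) != targets.size:
        raise ValueError("one target correlation per receptor required")

    rng = np.random.default_rng(seed)
    y = atrophy_map.to_numpy(dtype=float)
    yz = (y - y.mean()) / y.std()
    n = y.size

    cols = {}
    for name, r in zip(names, targets):
        noise = rng.standard_normal(n)
        noise = (noise - noise.mean()) / noise.std()
        raw = r * yz + np.sqrt(1.0 - r**2) * noise
        scale = rng.uniform(5.0, 30.0)
        offset = rng.uniform(20.0, 100.0)
        cols[name] = offset + scale * raw
    dens = pd.DataFrame(cols, index=atrophy_map.index)
    dens.index.name = "region"

    truth = SyntheticTruth(
        receptor_target_correlations=list(targets), seed=seed
    )
    return ReceptorAtlas(densities=dens, systems=systems), truth


def make_pathology_sets(
    background: list[str],
    signature_genes: list[str],
    overlap_fraction: float,
    set_size: int,
    seed: int = 0,
) -> set[str]:
    """Draw a synthetic pathology gene list with planted signature overlap.

    Returns ``set_size`` genes containing ``round(overlap_fraction *
    len(signature_genes))`` signature genes; the remainder is sampled
    uniformly from the background excluding the signature.
    """
    bg = list(dict.fromkeys(background))
    sig = list(dict.fromkeys(signature_genes))
    missing = set(sig) - set(bg)
    if missing:
        raise ValueError(
            f"signature genes absent from background: {sorted(missing)[:5]}"
        )
    if set_size > len(bg):
        raise ValueError("set_size exceeds background size")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    n_sig = round(overlap_fraction * len(sig))
    if n_sig > set_size:
        raise ValueError("requested signature overlap exceeds set_size")
    non_sig = sorted(set(bg) - set(sig))
    if set_size - n_sig > len(non_sig):
        raise ValueError("background too small outside the signature")

    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(sorted(sig), size=n_sig, replace=False)) if n_sig else []
    chosen += list(rng.choice(non_sig, size=set_size - n_sig, replace=False))
    return set(chosen)
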