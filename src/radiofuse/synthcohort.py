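"""Synthetic radiogenomic cohorts with planted, recoverable structure.

The generator emulates the shape of a CT radiogenomics study without any
real data: ellipsoidal tumours with smooth sinusoidal texture in noisy
volumes, histology labels driven by texture amplitude tertiles, T stage
assigned by tumour-volume quartile, and gene expression where a chosen
subset of genes is rank-coupled to realised image feature values at a
configurable Spearman strength.  All randomness flows from a single seed,
so identical inputs give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import VolumeWithMask
from .hcfeat import HCConfig, extract_hc, hc_feature_names

HISTOLOGY_CLASSES = ("squamous", "adeno", "other")
T_STAGES = ("T1", "T2", "T3", "T4")


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic tumour volume.

    ``texture_scale`` is the amplitude (HU-like units) of the smooth
    intra-tumour intensity modulation; ``background_noise_sd`` applies
    everywhere.  Intensities are clipped to ``intensity_range``.
    """

    grid_shape: tuple[int, int, int] = (44, 44, 44)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes: tuple[float, float, float] = (10.0, 10.0, 10.0)
    centre: tuple[float, float, float] | None = None  # default: grid centre
    texture_scale: float = 60.0
    background_noise_sd: float = 20.0
    base_intensity: float = 1024.0
    intensity_range: tuple[float, float] = (0.0, 4096.0)
    n_texture_waves: int = 4

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi_axes must be positive, got {self.semi_axes}")
        if self.intensity_range[0] >= self.intensity_range[1]:
            raise ValueError("intensity_range lower bound must be < upper")
        if self.centre is None:
            self.centre = tuple(
                (n - 1) / 2 * s for n, s in zip(self.grid_shape, self.spacing)
            )
        extent = [(n - 1) * s for n, s in zip(self.grid_shape, self.spacing)]
        for ax, (c, a, e) in enumerate(zip(self.centre, self.semi_axes, extent)):
            if not (0 <= c <= e):
                raise ValueError(f"centre outside volume extent on axis {ax}")
            if c - a < 0 or c + a > e:
                raise ValueError(
                    f"ellipsoid exceeds grid extent on axis {ax}: "
                    f"centre {c} +/- semi-axis {a} vs extent [0, {e}]"
                )


@dataclass(frozen=True)
class PlantedLink:
    """Ground-truth coupling of one gene to one image feature."""

    gene_id: str
    feature_id: str
    strength: float  # target Spearman correlation in [-1, 1]

    def __post_init__(self) -> None:
        if not -1.0 <= self.strength <= 1.0:
            raise ValueError(f"|strength| must be <= 1, got {self.strength}")

    @property
    def direction(self) -> int:
        return 1 if self.strength >= 0 else -1


@dataclass
class SyntheticCohort:
    """Everything one pipeline run needs, with the planted ground truth."""

    volumes_masks: list[VolumeWithMask]
    clinical: pd.DataFrame  # patient_id, histology, t_stage
    expression: pd.DataFrame  # genes x patients
    gene_sets: dict[str, list[str]]
    truth: dict
    hc_features: pd.DataFrame  # patients x 431, cached from generation

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical["patient_id"])


def generate_phantom(spec: PhantomSpec, seed: int) -> VolumeWithMask:
    """Voxelise an ellipsoidal textured tumour inside a noisy volume.

    The mask contains voxels whose centres satisfy the strict ellipsoid
    inequality sum(((x - c)/a)^2) < 1; the tumour signal is the base
    intensity plus a seeded sum of low-frequency sinusoids, background is
    noise only, and everything is clipped to the storable range.
    """
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)),
        indexing="ij",
    )
    u = sum(((g - c) / a) ** 2
            for g, c, a in zip(grids, spec.centre, spec.semi_axes))
    mask = u < 1.0

    texture = np.zeros(spec.grid_shape)
    for _ in range(spec.n_texture_waves):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wavelength = rng.uniform(8.0, 20.0)  # mm, low frequency vs tumour size
        phase = rng.uniform(0, 2 * np.pi)
        arg = sum(g * d for g, d in zip(grids, direction))
        texture += np.sin(2 * np.pi * arg / wavelength + phase)
    texture *= spec.texture_scale / np.sqrt(spec.n_texture_waves)

    noise = rng.normal(0.0, spec.background_noise_sd, size=spec.grid_shape)
    intens = np.where(mask, spec.base_intensity + texture, 0.0) + noise
    intens = np.clip(intens, *spec.intensity_range)
    return VolumeWithMask(intensities=intens, mask=mask, spacing=spec.spacing)


def _calibrated_gene(feature: np.ndarray, strength: float,
                     rng: np.random.Generator) -> np.ndarray:
    """A standard-scale gene vector whose realised Spearman correlation
    with ``feature`` is calibrated to ``strength``.

    The gene is a mixture of the feature's Gaussian rank scores and
    independent Gaussian rank noise; the mixing weight is chosen by a grid
    search so the sample (not just population) Spearman matches the target.
    At |strength| = 1 the mixture degenerates to an exact monotone copy.
    """
    n = len(feature)
    ranks = sps.rankdata(feature)
    z_f = sps.norm.ppf(ranks / (n + 1))
    sign = 1.0 if strength >= 0 else -1.0
    target = abs(strength)
    if target == 1.0:
        return sign * z_f
    eps = rng.normal(size=n)
    best_a, best_err = 0.0, np.inf
    for a in np.linspace(0.0, 1.0, 201):
        g = a * z_f + np.sqrt(1 - a * a) * eps
        rho = sps.spearmanr(feature, g).statistic
        err = abs(rho - target)
        if err < best_err:
            best_a, best_err = a, err
    g = best_a * z_f + np.sqrt(1 - best_a ** 2) * eps
    return sign * g


def generate_cohort(n_patients: int, n_genes: int,
                    links: list[PlantedLink], seed: int,
                    grid_shape: tuple[int, int, int] = (44, 44, 44),
                    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    hc_config: HCConfig | None = None,
                    n_gene_sets: int = 0,
                    gene_set_size_range: tuple[int, int] = (15, 30),
                    ) -> SyntheticCohort:
    """Generate a full synthetic cohort with planted radiogenomic links.

    Tumour semi-axes vary across patients (driving volume and hence T
    stage, assigned by volume quartile); texture amplitude varies
    continuously and its tertiles define the histology label, so
    texture-sensitive image features carry the class signal the supervised
    selection stages condition on.  Linked genes are rank-coupled to the
    *realised* feature values extracted from the generated volumes.
    """
    if n_patients < 10:
        raise ValueError(f"n_patients must be >= 10, got {n_patients}")
    catalogue = set(hc_feature_names(hc_config))
    gene_ids = [lk.gene_id for lk in links]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("link gene_ids must be unique")
    for lk in links:
        if lk.feature_id not in catalogue:
            raise ValueError(
                f"link feature_id {lk.feature_id!r} is not in the "
                "handcrafted feature catalogue"
            )

    rng = np.random.default_rng(seed)
    patient_ids = [f"P{i:03d}" for i in range(n_patients)]

    texture_scales = rng.uniform(20.0, 120.0, size=n_patients)
    phantom_seeds = rng.integers(0, 2**31 - 1, size=n_patients)

    # semi-axis range scaled to the grid so the ellipsoid always fits
    min_extent = min((n - 1) * s for n, s in zip(grid_shape, spacing))
    semi_hi = min(14.0, min_extent / 2 - 1.5)
    semi_lo = min(6.0, 0.6 * semi_hi)
    volumes: list[VolumeWithMask] = []
    for i in range(n_patients):
        semi = rng.uniform(semi_lo, semi_hi, size=3)
        spec = PhantomSpec(
            grid_shape=grid_shape, spacing=spacing,
            semi_axes=tuple(semi), texture_scale=float(texture_scales[i]),
        )
        vm = generate_phantom(spec, int(phantom_seeds[i]))
        vm.patient_id = patient_ids[i]
        volumes.append(vm)

    hc = pd.DataFrame(
        [extract_hc(vm, hc_config).values for vm in volumes],
        index=patient_ids, columns=hc_feature_names(hc_config),
    )

    # histology = texture-amplitude tertile; T stage = volume quartile
    tert = pd.qcut(texture_scales, 3, labels=False)
    histology = [HISTOLOGY_CLASSES[t] for t in tert]
    vol_quart = pd.qcut(hc["shape.volume_mm3"], 4, labels=False)
    t_stage = [T_STAGES[q] for q in vol_quart]
    clinical = pd.DataFrame({
        "patient_id": patient_ids, "histology": histology, "t_stage": t_stage,
    })

    # expression: linked genes rank-coupled to realised features, the rest
    # independent of all images
    all_genes = [f"G{i:04d}" for i in range(n_genes)]
    name_map = {}
    for j, lk in enumerate(links):
        name_map[all_genes[j]] = lk.gene_id
    gene_names = [name_map.get(g, g) for g in all_genes]
    if len(set(gene_names)) != n_genes:
        raise ValueError("link gene_ids collide with generated gene names")

    expr = np.empty((n_genes, n_patients))
    mus = rng.uniform(4.0, 12.0, size=n_genes)
    sds = rng.uniform(0.5, 2.0, size=n_genes)
    for j in range(n_genes):
        if j < len(links):
            z = _calibrated_gene(hc[links[j].feature_id].to_numpy(),
                                 links[j].strength, rng)
            # monotone remap to a filter-safe marginal (preserves ranks,
            # hence the calibrated Spearman): uniform shape maximises
            # histogram entropy; mean and dispersion in the upper range
            z = (sps.rankdata(z) / (n_patients + 1) - 0.5) * np.sqrt(12)
            mu_j = rng.uniform(8.0, 12.0)
            sd_j = rng.uniform(1.2, 2.0)
        else:
            z = rng.normal(size=n_patients)
            mu_j, sd_j = mus[j], sds[j]
        expr[j] = mu_j + sd_j * z
    expression = pd.DataFrame(expr, index=gene_names, columns=patient_ids)

    planted_genes = [lk.gene_id for lk in links]
    gene_sets: dict[str, list[str]] = {}
    planted_set_ids: list[str] = []
    if n_gene_sets > 0:
        # plant enriched sets only when the planted-gene pool can supply
        # >= 80% of members at the smallest allowed set size
        pool_supports = int(len(planted_genes) / 0.9) >= gene_set_size_range[0]
        gene_sets, planted_set_ids = generate_gene_sets(
            gene_names, planted_genes, n_gene_sets, gene_set_size_range,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_planted=min(2, n_gene_sets) if pool_supports else 0,
        )

    truth = {
        "links": [
            {"gene_id": lk.gene_id, "feature_id": lk.feature_id,
             "strength": lk.strength, "direction": lk.direction}
            for lk in links
        ],
        "planted_set_ids": planted_set_ids,
    }
    return SyntheticCohort(
        volumes_masks=volumes, clinical=clinical, expression=expression,
        gene_sets=gene_sets, truth=truth, hc_features=hc,
    )


def generate_gene_sets(expression_genes: list[str], planted_genes: list[str],
                       n_sets: int, size_range: tuple[int, int], seed: int,
                       n_planted: int = 2,
                       planted_fraction: float = 0.9,
                       ) -> tuple[dict[str, list[str]], list[str]]:
    """Gene-set collection with ``n_planted`` sets enriched for the planted
    genes (>= 80% of members drawn from them) and uniform decoy sets.
    """
    lo, hi = size_range
    if lo < 2 or hi > len(expression_genes):
        raise ValueError("size_range must lie within [2, n_genes]")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    planted_ids: list[str] = []
    others = [g for g in expression_genes if g not in set(planted_genes)]
    # planted sets cannot be larger than the pool supports at the
    # requested planted fraction
    max_planted_size = int(len(planted_genes) / planted_fraction)
    for i in range(n_sets):
        name = f"GS{i:03d}"
        if i < n_planted:
            if max_planted_size < lo:
                raise ValueError(
                    f"planted_genes ({len(planted_genes)}) smaller than the "
                    f"requested planted-set size (>= {lo} members, "
                    f">= {planted_fraction:.0%} planted)"
                )
            size = int(rng.integers(lo, min(hi, max_planted_size) + 1))
            n_from_planted = min(int(np.ceil(planted_fraction * size)),
                                 size, len(planted_genes))
            members = list(rng.choice(planted_genes, n_from_planted,
                                      replace=False))
            members += list(rng.choice(others, size - n_from_planted,
                                       replace=False))
            planted_ids.append(name)
        else:
            size = int(rng.integers(lo, hi + 1))
            members = list(rng.choice(expression_genes, size, replace=False))
        sets[name] = members
    return sets, planted_ids


# ------------------------------------------------------------------- disk I/O

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Persist a cohort as plain files: NIfTI pairs, CSV/TSV, GMT, JSON."""
    from .gsea import write_gmt

    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    for vm in cohort.volumes_masks:
        vm.to_nifti(out / "volumes" / f"{vm.patient_id}_vol.nii.gz",
                    out / "volumes" / f"{vm.patient_id}_mask.nii.gz")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.expression.to_csv(out / "expression.tsv", sep="\t",
                             index_label="gene")
    if cohort.gene_sets:
        write_gmt(cohort.gene_sets, out / "gene_sets.gmt")
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2))
    cohort.hc_features.to_csv(out / "features_hc.csv", index_label="patient_id")
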