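"""Group comparison of behavioural maps.

Per-individual densities on a shared grid support pointwise two-sample
tests between groups: a two-sided Wilcoxon rank-sum test at every grid
cell flags locations where the median density differs (p below alpha,
uncorrected, with a Benjamini-Hochberg companion mask since pointwise
testing on a smoothed map is anticonservative).  Region-normalized
densities allow fine-scale comparison inside one portion of the map, and
phase-averaged orbits can be contrasted between groups separately in
shape (per-bin SEM overlap) and in frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behaviormap import BehaviorDensity, estimate_density
from .phase import PhaseOrbit, PhaseSeries, phase_average

__all__ = [
    "IndividualDensitySet",
    "SignificanceMask",
    "per_individual_density",
    "region_normalized_pdf",
    "wilcoxon_significance_map",
    "compare_group_orbits",
]


@dataclass
class IndividualDensitySet:
    """Per-individual densities on one shared grid, with group labels."""

    densities: list[BehaviorDensity]
    groups: np.ndarray  # one label per individual
    extent: tuple[float, float, float, float]
    sigma: float

    def stack(self, group=None) -> np.ndarray:
        idx = range(len(self.densities)) if group is None else np.flatnonzero(
            self.groups == group
        )
        return np.stack([self.densities[i].grid for i in idx])

    def group_mean(self, group) -> np.ndarray:
        return self.stack(group).mean(axis=0)

    def difference_map(self, group_a, group_b) -> np.ndarray:
        return self.group_mean(group_a) - self.group_mean(group_b)


@dataclass
class SignificanceMask:
    """Pointwise significance of a two-group density comparison."""

    mask: np.ndarray  # bool grid, p < alpha on testable cells
    fdr_mask: np.ndarray  # bool grid, Benjamini-Hochberg at alpha
    p_values: np.ndarray  # grid; NaN on untestable cells
    alpha: float
    difference: np.ndarray  # median(group A) - median(group B)
    testable: np.ndarray  # bool grid


def per_individual_density(
    z_per_individual: list[np.ndarray],
    groups: list | np.ndarray,
    sigma: float = 1.5,
    grid_size: int = 201,
    min_frames: int = 10,
    extent: tuple[float, float, float, float] | None = None,
) -> IndividualDensitySet:
    """Estimate each individual's behavioural density on a shared grid.

    Individuals with fewer than ``min_frames`` frames are excluded with a
    warning.  The shared extent defaults to the pooled data extent plus a
    3-sigma margin.
    """
    groups = np.asarray(groups)
    keep = [i for i, z in enumerate(z_per_individual) if len(z) >= min_frames]
    if len(keep) < len(z_per_individual):
        warnings.warn(
            f"excluded {len(z_per_individual) - len(keep)} individual(s) with "
            f"fewer than {min_frames} frames",
            stacklevel=2,
        )
    if len({g for g in groups[keep]}) and any(
        np.sum(groups[keep] == g) < 2 for g in np.unique(groups[keep])
    ):
        raise ValueError("need at least 2 individuals per group")
    if extent is None:
        allz = np.vstack([z_per_individual[i] for i in keep])
        pad = 3.0 * sigma
        extent = (
            allz[:, 0].min() - pad,
            allz[:, 0].max() + pad,
            allz[:, 1].min() - pad,
            allz[:, 1].max() + pad,
        )
    dens = [
        estimate_density(z_per_individual[i], sigma=sigma, grid_size=grid_size, extent=extent)
        for i in keep
    ]
    return IndividualDensitySet(
        densities=dens, groups=groups[keep], extent=extent, sigma=sigma
    )


def region_normalized_pdf(
    density: BehaviorDensity, region_mask: np.ndarray
) -> BehaviorDensity:
    """Restrict a density to a region and renormalize it to integrate to
    one there (zero outside)."""
    mask = np.asarray(region_mask, bool)
    if mask.shape != density.grid.shape:
        raise ValueError("mask shape does not match the density grid")
    if not mask.any():
        raise ValueError("empty region mask")
    dx, dy = density.cell_size
    g = np.where(mask, density.grid, 0.0)
    mass = g.sum() * dx * dy
    if mass <= 0:
        raise ValueError("zero probability mass inside the mask")
    return BehaviorDensity(grid=g / mass, extent=density.extent, sigma=density.sigma)


def wilcoxon_significance_map(
    dset: IndividualDensitySet,
    alpha: float = 0.01,
    group_a=None,
    group_b=None,
) -> SignificanceMask:
    """Pointwise two-sided Wilcoxon rank-sum test between two groups of
    per-individual densities.

    Cells are testable where at least one individual (either group) has a
    nonzero value — so a behaviour present in only one group is testable
    there; elsewhere p is NaN.  The primary mask thresholds the
    uncorrected p-values at ``alpha``; a Benjamini-Hochberg FDR-adjusted
    companion mask is reported alongside.
    """
    labels = np.unique(dset.groups)
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError("specify group_a and group_b for >2 groups")
        group_a, group_b = labels[0], labels[1]
    A = dset.stack(group_a)
    B = dset.stack(group_b)
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 individuals per group")
    testable = (A > 0).any(axis=0) | (B > 0).any(axis=0)
    p = np.full(A.shape[1:], np.nan)
    # Mann-Whitney U == Wilcoxon rank-sum, with tie correction (many cells
    # hold exact zeros for several individuals)
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            A, B, axis=0, alternative="two-sided", method="asymptotic"
        )
    pv = np.asarray(res.pvalue)
    # constant-across-individuals cells (all ties) give NaN statistics: p = 1
    ties = np.ptp(np.concatenate([A, B], axis=0), axis=0) == 0
    pv = np.where(ties, 1.0, pv)
    p[testable] = pv[testable]
    mask = testable & (p < alpha)
    fdr_mask = np.zeros_like(mask)
    flat = p[testable]
    if flat.size:
        adj = stats.false_discovery_control(flat, method="bh")
        tmp = np.zeros(flat.size, dtype=bool)
        tmp[adj < alpha] = True
        fdr_mask[testable] = tmp
    diff = np.median(A, axis=0) - np.median(B, axis=0)
    return SignificanceMask(
        mask=mask,
        fdr_mask=fdr_mask,
        p_values=p,
        alpha=alpha,
        difference=diff,
        testable=testable,
    )


def significant_components(mask: np.ndarray, min_cells: int = 20) -> np.ndarray:
    """Label connected components of a significance mask, discarding
    components smaller than ``min_cells`` cells."""
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    if n == 0:
        return labels
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_cells) + 1
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def compare_group_orbits(
    bouts_a: list[tuple[np.ndarray, PhaseSeries]],
    bouts_b: list[tuple[np.ndarray, PhaseSeries]],
    n_bins: int = 50,
    sem_factor: float = 2.0,
) -> tuple[PhaseOrbit, PhaseOrbit, np.ndarray, float, float]:
    """Contrast the phase-averaged orbits of one behaviour between groups.

    Returns ``(orbit_a, orbit_b, separated, freq_diff, freq_diff_se)``
    where ``separated[k, b]`` is True when the two group means differ by
    more than ``sem_factor`` combined SEMs in mode k, phase bin b, and
    the frequency difference carries its standard error (shape and
    frequency can differ independently).
    """
    if len(bouts_a) < 5 or len(bouts_b) < 5:
        raise ValueError("need at least 5 bouts per group")
    oa = phase_average(bouts_a, n_bins=n_bins)
    ob = phase_average(bouts_b, n_bins=n_bins)
    gap = np.abs(oa.mean - ob.mean)
    pooled = np.sqrt(oa.sem**2 + ob.sem**2)
    separated = gap > sem_factor * pooled
    freq_diff = oa.mean_frequency - ob.mean_frequency
    freq_se = float(np.hypot(oa.frequency_sem, ob.frequency_sem))
    return oa, ob, separated, float(freq_diff), freq_se
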