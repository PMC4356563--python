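"""Cluster statistics over scan dipoles and sEEG-referenced validation scores.

Implements centroid dipoles (mean location, renormalized mean orientation),
single-pass mean+2·SD outlier pruning, the Square Distance Index

    SDI_i = (100 / N) · Σ_j 1 / (d_ij² + 1),   d_ij in mm,

which is 100 when every dipole coincides with contact i and decays with the
inverse square distance, and within-radius contact coverage counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError


@dataclass
class DipoleCluster:
    """Homogeneous set of scan dipoles (one modality, time point and group)."""

    locations_mm: np.ndarray  # (n, 3)
    orientations: np.ndarray | None = None  # (n, 3) unit vectors
    modality: str = ""
    time_ms: float = 0.0
    group: int = 0

    def __post_init__(self) -> None:
        self.locations_mm = np.atleast_2d(np.asarray(self.locations_mm, float))
        if self.orientations is not None:
            self.orientations = np.atleast_2d(np.asarray(self.orientations, float))

    def __len__(self) -> int:
        return self.locations_mm.shape[0]


@dataclass
class CentroidDipole:
    location_mm: np.ndarray
    orientation: np.ndarray | None = None
    orientation_defined: bool = True


@dataclass
class SDITable:
    contact_ids: list
    sdi: np.ndarray  # per-contact SDI (NaN where undefined)
    n_within: np.ndarray  # dipole counts within the coverage radius
    fraction_within: np.ndarray
    radius_mm: float = 10.0

    def summary(self) -> tuple:
        return summarize_sdi(self.sdi)

    @property
    def n_contacts_covered(self) -> int:
        return int(np.sum(self.n_within >= 1))


def centroid(cluster: DipoleCluster) -> CentroidDipole:
    """Mean location; orientation = renormalized mean of sign-aligned units.

    Orientations are sign-aligned to the first member before averaging, since
    a dipole and its negation describe the same generator.
    """
    if len(cluster) == 0:
        raise InputError("empty cluster has no centroid")
    loc = cluster.locations_mm.mean(axis=0)
    if cluster.orientations is None:
        return CentroidDipole(location_mm=loc, orientation=None)
    ori = cluster.orientations.copy()
    signs = np.sign(ori @ ori[0])
    signs[signs == 0] = 1.0
    mean_ori = (ori * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean_ori)
    if norm < 1e-12:
        warnings.warn("orientations cancel; centroid orientation undefined", stacklevel=2)
        return CentroidDipole(location_mm=loc, orientation=None, orientation_defined=False)
    return CentroidDipole(location_mm=loc, orientation=mean_ori / norm)


def prune_outliers(cluster: DipoleCluster) -> tuple:
    """Single-pass mean+2·SD distance filter against the cluster centroid.

    Distances use the population SD; members strictly beyond mean + 2·SD are
    removed.  The rule is applied once (no re-iteration).  Clusters smaller
    than 2 are returned unchanged with a warning.
    """
    n = len(cluster)
    if n < 2:
        warnings.warn("cluster too small to prune", stacklevel=2)
        return cluster, DipoleCluster(np.empty((0, 3)))
    cen = centroid(cluster)
    d = np.linalg.norm(cluster.locations_mm - cen.location_mm, axis=1)
    mu, sd = d.mean(), d.std()  # population SD
    keep = d <= mu + 2 * sd
    kept = DipoleCluster(
        cluster.locations_mm[keep],
        None if cluster.orientations is None else cluster.orientations[keep],
        cluster.modality,
        cluster.time_ms,
        cluster.group,
    )
    removed = DipoleCluster(
        cluster.locations_mm[~keep],
        None if cluster.orientations is None else cluster.orientations[~keep],
        cluster.modality,
        cluster.time_ms,
        cluster.group,
    )
    return kept, removed


def sdi(dipole_locations_mm: np.ndarray, contact_mm: np.ndarray) -> float:
    """Square Distance Index of one contact against N dipoles (distances in mm)."""
    locs = np.atleast_2d(np.asarray(dipole_locations_mm, float))
    if locs.shape[0] == 0:
        raise InputError("SDI undefined for zero dipoles")
    d = np.linalg.norm(locs - np.asarray(contact_mm, float), axis=1)
    return float(100.0 / d.size * np.sum(1.0 / (d**2 + 1.0)))


def coverage(
    dipole_locations_mm: np.ndarray,
    contacts_mm: np.ndarray,
    contact_ids: list | None = None,
    radius_mm: float = 10.0,
    strict: bool = False,
) -> SDITable:
    """Per-contact SDI plus within-radius dipole counts and fractions.

    ``strict`` switches the coverage ball from closed (d <= radius, default)
    to open (d < radius); on real coordinates the two coincide almost surely.
    """
    if radius_mm <= 0:
        raise InputError("radius must be positive")
    locs = np.atleast_2d(np.asarray(dipole_locations_mm, float))
    contacts = np.atleast_2d(np.asarray(contacts_mm, float))
    ids = contact_ids if contact_ids is not None else [str(i) for i in range(len(contacts))]
    n_dip = locs.shape[0]
    sdi_vals = np.full(len(contacts), np.nan)
    n_within = np.zeros(len(contacts), int)
    frac = np.zeros(len(contacts))
    for i, c in enumerate(contacts):
        if n_dip:
            d = np.linalg.norm(locs - c, axis=1)
            sdi_vals[i] = 100.0 / n_dip * np.sum(1.0 / (d**2 + 1.0))
            inside = d < radius_mm if strict else d <= radius_mm
            n_within[i] = int(np.sum(inside))
            frac[i] = n_within[i] / n_dip
    return SDITable(
        contact_ids=list(ids),
        sdi=sdi_vals,
        n_within=n_within,
        fraction_within=frac,
        radius_mm=radius_mm,
    )


def summarize_sdi(sdi_values: np.ndarray) -> tuple:
    """(mean, population SD) of the per-contact SDIs, ignoring missing ones."""
    v = np.asarray(sdi_values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InputError("no contact has a defined SDI")
    return float(v.mean()), float(v.std())
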