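"""Synthetic feature tables with planted class, site and confounded signal.

Real slide collections carry two label structures at once: the diagnosis a
retrieval system should respect, and the acquisition site whose signature
leaks into learned features. This generator emulates that situation in
feature space so bias removal can be tested without any real cohort:

* ``class`` dims shift with the diagnosis centroid,
* ``site`` dims shift with the institution centroid,
* ``confounded`` dims shift with both (their means add),
* ``noise`` dims are pure Gaussian noise.

Site-class confounding is modeled on the label distribution: each
diagnosis draws its sites from a skewed distribution that concentrates on
a diagnosis-specific block of sites as ``confounding`` rises (0 = fully
independent, 1 = disjoint blocks). This mirrors the empirical observation
that contributing institutions have correlated case mixes, which is what
lets a retrieval model cheat off site signal.

Centroids are scaled rows of a seeded random orthonormal frame. Effect
sizes are expressed per informative dimension, the usual convention in
batch-effect simulation: an effect of e over a block of d dims places
every pair of centroids e * sqrt(d) noise standard deviations apart,
exactly as if each dim of the block carried an e-SD mean shift. Signal
therefore pools across an informative block the way it does across
correlated deep-feature channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FeatureTable, split_dataset

ROLE_ORDER = ("class", "site", "confounded", "noise")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults are the desk-scale benchmark conditions."""

    n_per_diagnosis_per_split: tuple[int, int, int] = (60, 20, 20)
    diagnoses: tuple[str, ...] = ("LUAD", "KIRC", "BRCA", "GBM")
    sites: tuple[str, ...] = ("site1", "site2", "site3", "site4", "site5", "site6")
    d_class: int = 16
    d_site: int = 16
    d_confounded: int = 8
    d_noise: int = 88
    class_effect: float = 2.0  # per-class-dim mean shift, in noise SDs
    site_effect: float = 2.0  # per-site-dim mean shift, in noise SDs
    confounding: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.d_class, self.d_site, self.d_confounded, self.d_noise) < 0:
            raise ValueError("dimension counts must be nonnegative")
        if self.D < 1:
            raise ValueError("total dimension must be >= 1")
        if len(self.diagnoses) < 2 or len(self.sites) < 2:
            raise ValueError("need at least 2 diagnoses and 2 sites")
        if not 0.0 <= self.confounding <= 1.0:
            raise ValueError("confounding must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.confounding == 1.0 and len(self.diagnoses) > len(self.sites):
            raise ValueError(
                "confounding=1 requires at least as many sites as diagnoses "
                "(each diagnosis needs a disjoint site block)"
            )

    @property
    def D(self) -> int:
        return self.d_class + self.d_site + self.d_confounded + self.d_noise


@dataclass(frozen=True)
class GroundTruth:
    """Per-dimension role annotation aligned with the feature columns."""

    roles: tuple[str, ...]

    def indices(self, role: str) -> np.ndarray:
        if role not in ROLE_ORDER:
            raise ValueError(f"unknown role {role!r}")
        return np.flatnonzero(np.asarray(self.roles) == role)

    def oracle_mask(self, *roles: str) -> np.ndarray:
        """Binary mask selecting exactly the dims of the given roles."""
        mask = np.zeros(len(self.roles), dtype=np.uint8)
        for role in roles:
            mask[self.indices(role)] = 1
        return mask


def _centroid_frame(
    n_labels: int, n_dims: int, effect: float, rng: np.random.Generator
) -> np.ndarray:
    """n_labels centroids in R^n_dims, pairwise distance effect * sqrt(n_dims).

    Rows of a random orthonormal frame scaled so each pair of centroids is
    separated as if every dim of the block carried an ``effect``-SD mean
    shift (orthonormal vectors are sqrt(2) apart before scaling).
    """
    if effect == 0:
        return np.zeros((n_labels, n_dims))
    if n_dims < n_labels:
        raise ValueError(
            f"cannot place {n_labels} equidistant centroids in {n_dims} dims; "
            "need at least as many dims as labels"
        )
    gauss = rng.normal(size=(n_dims, n_dims))
    q, _ = np.linalg.qr(gauss)
    separation = effect * np.sqrt(n_dims)
    return q[:n_labels] * (separation / np.sqrt(2.0))


def _site_distribution(spec: SyntheticSpec) -> np.ndarray:
    """Diagnosis-conditional site probabilities, skew set by ``confounding``."""
    n_d, n_s = len(spec.diagnoses), len(spec.sites)
    uniform = np.full(n_s, 1.0 / n_s)
    probs = np.empty((n_d, n_s))
    # round-robin site blocks: site s belongs to diagnosis s mod n_d
    blocks = [[s for s in range(n_s) if s % n_d == c] for c in range(n_d)]
    for c in range(n_d):
        if blocks[c]:
            block = np.zeros(n_s)
            block[blocks[c]] = 1.0 / len(blocks[c])
        else:
            block = uniform  # more diagnoses than sites; only valid when confounding < 1
        probs[c] = (1.0 - spec.confounding) * uniform + spec.confounding * block
    return probs


def generate_biased_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw a labeled feature table plus its per-dimension ground truth.

    Deterministic for a fixed spec (including its seed). Columns are laid
    out in role order: class, site, confounded, noise. Splits are assigned
    by the diagnosis-stratified splitter, never balanced on site.
    """
    rng = np.random.default_rng(spec.seed)
    n_d, n_s = len(spec.diagnoses), len(spec.sites)
    roles = (
        ("class",) * spec.d_class
        + ("site",) * spec.d_site
        + ("confounded",) * spec.d_confounded
        + ("noise",) * spec.d_noise
    )
    truth = GroundTruth(roles)

    class_c = _centroid_frame(n_d, spec.d_class, spec.class_effect, rng) if spec.d_class else np.zeros((n_d, 0))
    site_c = _centroid_frame(n_s, spec.d_site, spec.site_effect, rng) if spec.d_site else np.zeros((n_s, 0))
    if spec.d_confounded:
        conf_class = _centroid_frame(n_d, spec.d_confounded, spec.class_effect, rng)
        conf_site = _centroid_frame(n_s, spec.d_confounded, spec.site_effect, rng)
    else:
        conf_class = np.zeros((n_d, 0))
        conf_site = np.zeros((n_s, 0))

    site_probs = _site_distribution(spec)
    n_per_diag = int(sum(spec.n_per_diagnosis_per_split))
    n_total = n_per_diag * n_d

    X = np.empty((n_total, spec.D))
    diagnosis: list[str] = []
    site: list[str] = []
    row = 0
    for c in range(n_d):
        sites_drawn = rng.choice(n_s, size=n_per_diag, p=site_probs[c])
        for s in sites_drawn:
            mu = np.concatenate(
                [class_c[c], site_c[s], conf_class[c] + conf_site[s], np.zeros(spec.d_noise)]
            )
            X[row] = mu + rng.normal(scale=spec.noise_sd, size=spec.D)
            diagnosis.append(spec.diagnoses[c])
            site.append(spec.sites[int(s)])
            row += 1

    width = len(str(n_total - 1))
    table = FeatureTable(
        sample_ids=tuple(f"s{i:0{width}d}" for i in range(n_total)),
        X=X,
        diagnosis=tuple(diagnosis),
        site=tuple(site),
        tumor_type=("synthetic",) * n_total,
        split=("train",) * n_total,  # placeholder; reassigned below
        provenance=f"synthetic generator, seed={spec.seed}",
    )
    fractions = tuple(n / n_per_diag for n in spec.n_per_diagnosis_per_split)
    # derived split seed stays deterministic and below 2**31
    return split_dataset(table, fractions, seed=(spec.seed * 9973 + 7) % (2**31)), truth


def ground_truth_report(mask, truth: GroundTruth) -> dict[str, dict[str, float]]:
    """How a mask overlaps the planted structure.

    ``selected_fraction_of_role``: per role, the fraction of that role's
    dims with the bit set (recall of the role). ``composition``: of the
    selected dims, the fraction belonging to each role.
    """
    m = np.asarray(mask).astype(bool)
    if m.shape != (len(truth.roles),):
        raise ValueError("mask length does not match ground truth")
    n_selected = int(m.sum())
    recall: dict[str, float] = {}
    composition: dict[str, float] = {}
    for role in ROLE_ORDER:
        idx = truth.indices(role)
        recall[role] = float(m[idx].mean()) if idx.size else 0.0
        composition[role] = float(m[idx].sum() / n_selected) if n_selected else 0.0
    return {"selected_fraction_of_role": recall, "composition": composition}
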