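"""Seeded two-group cohorts of ROI time series.

The generator emulates a resting-state fMRI case/control study design at
the region-of-interest level: a modular ground-truth coupling network is
shared by all subjects, a second variant of it carries a localized group
effect (couplings incident to a small set of designated regions are scaled
by a multiplier), and each subject's BOLD-like time series are drawn from a
multivariate Gaussian whose covariance is a positive-definite lift of that
subject's coupling matrix, temporally smoothed with an AR(1) filter plus
white observation noise.

Defaults mirror the emulated study: 130 control-like (label 0) and 156
case-like (label 1) subjects, 90 AAL regions, 950 retained timepoints at a
0.5 s sampling interval, and eight effect regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .atlas import DEFAULT_EFFECT_REGIONS, default_labels
from ._seeds import derive_seed

__all__ = [
    "CohortConfig",
    "GroundTruthNetwork",
    "RoiTimeSeries",
    "build_group_network",
    "inject_group_effect",
    "sample_subject_timeseries",
    "generate_cohort",
    "write_cohort",
]

# Floor on the smallest eigenvalue of the subject covariance: the minimal
# positive-definite lift that keeps relative coupling structure intact.
_MIN_COV_EIGENVALUE = 0.1


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic two-group cohort."""

    n_group_a: int = 130
    n_group_b: int = 156
    n_regions: int = 90
    n_timepoints: int = 950
    tr_seconds: float = 0.5
    effect_regions: tuple[int, ...] = DEFAULT_EFFECT_REGIONS
    effect_multiplier: float = 0.85
    subject_jitter_sd: float = 0.02
    noise_sd: float = 0.3
    ar1_coefficient: float = 0.3
    seed: int = 0
    # ground-truth network structure
    n_modules: int = 6
    within_weight: float = 0.3
    between_weight: float = 0.05
    weight_sd: float = 0.05

    def validate(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_regions", "n_timepoints", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be positive")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.subject_jitter_sd < 0 or self.noise_sd < 0 or self.weight_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_modules > self.n_regions:
            raise ValueError("n_modules cannot exceed n_regions")
        for r in self.effect_regions:
            if not 0 <= r < self.n_regions:
                raise ValueError(f"effect region index {r} outside [0, {self.n_regions})")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["effect_regions"] = list(self.effect_regions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "effect_regions" in d:
            d["effect_regions"] = tuple(int(r) for r in d["effect_regions"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Symmetric zero-diagonal coupling matrix with region names."""

    weights: np.ndarray
    region_labels: list[str]
    group_tag: str = "base"

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("network weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("network weights must be finite")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("network weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("network diagonal must be zero")
        if len(self.region_labels) != w.shape[0]:
            raise ValueError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's timepoints x regions signal matrix."""

    subject_id: str
    group_label: int
    values: np.ndarray
    tr_seconds: float
    region_labels: list[str]

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (timepoints x regions)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite entries")
        if len(self.region_labels) != self.values.shape[1]:
            raise ValueError("region_labels length must match column count")
        if self.group_label not in (0, 1):
            raise ValueError("group_label must be 0 or 1")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def _module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal module membership for each region."""
    return np.repeat(np.arange(n_modules), np.diff(np.linspace(0, n_regions, n_modules + 1).astype(int)))


def build_group_network(
    n_regions: int,
    n_modules: int = 1,
    within_weight: float = 0.3,
    between_weight: float = 0.05,
    weight_sd: float = 0.0,
    seed: int = 0,
    region_labels: list[str] | None = None,
    group_tag: str = "base",
) -> GroundTruthNetwork:
    """Build a modular symmetric coupling network.

    Couplings between regions in the same module are drawn around
    ``within_weight``, couplings across modules around ``between_weight``,
    each with independent Gaussian jitter of sd ``weight_sd`` applied to
    the upper triangle and mirrored.
    """
    if n_regions <= 0:
        raise ValueError("n_regions must be positive")
    if n_modules < 1 or n_modules > n_regions:
        raise ValueError("need 1 <= n_modules <= n_regions")
    if weight_sd < 0:
        raise ValueError("weight_sd must be non-negative")
    rng = np.random.default_rng(seed)
    modules = _module_assignment(n_regions, n_modules)
    same = modules[:, None] == modules[None, :]
    base = np.where(same, within_weight, between_weight).astype(float)
    jitter = rng.normal(0.0, weight_sd, size=(n_regions, n_regions)) if weight_sd > 0 else np.zeros((n_regions, n_regions))
    upper = np.triu(np.ones((n_regions, n_regions), dtype=bool), k=1)
    w = np.zeros((n_regions, n_regions))
    w[upper] = base[upper] + jitter[upper]
    w = w + w.T
    net = GroundTruthNetwork(
        weights=w,
        region_labels=region_labels if region_labels is not None else default_labels(n_regions),
        group_tag=group_tag,
    )
    net.validate()
    return net


def inject_group_effect(
    network: GroundTruthNetwork,
    effect_regions: tuple[int, ...] | list[int],
    effect_multiplier: float,
) -> GroundTruthNetwork:
    """Scale every coupling incident to an effect region by a multiplier.

    An entry touching two effect regions is scaled once, not twice, so a
    global region list with multiplier m yields exactly m times the input.
    """
    network.validate()
    n = network.n_regions
    for r in effect_regions:
        if not 0 <= r < n:
            raise ValueError(f"effect region index {r} outside [0, {n})")
    if effect_multiplier <= 0:
        raise ValueError("effect_multiplier must be positive")
    incident = np.zeros(n, dtype=bool)
    incident[list(effect_regions)] = True
    mask = incident[:, None] | incident[None, :]
    w = network.weights.copy()
    w[mask] *= effect_multiplier
    np.fill_diagonal(w, 0.0)
    out = replace(network, weights=w, group_tag=f"{network.group_tag}+effect")
    out.validate()
    return out


def _subject_covariance(coupling: np.ndarray) -> np.ndarray:
    """Minimal positive-definite lift: coupling + lambda*I with the smallest
    eigenvalue raised to at least 0.1."""
    min_eig = float(np.linalg.eigvalsh(coupling)[0])
    lam = max(0.0, _MIN_COV_EIGENVALUE - min_eig)
    return coupling + lam * np.eye(coupling.shape[0])


def sample_subject_timeseries(
    network: GroundTruthNetwork,
    n_timepoints: int,
    tr_seconds: float = 0.5,
    subject_jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    ar1_coefficient: float = 0.0,
    seed: int = 0,
    subject_id: str = "subject",
    group_label: int = 0,
) -> RoiTimeSeries:
    """Draw one subject's ROI time series from the generative model.

    The subject coupling is the group network plus symmetric Gaussian
    jitter; its positive-definite lift is the Gaussian covariance; rows are
    temporally smoothed with a first-order autoregressive filter and
    corrupted with white noise. Fully deterministic for a fixed seed.
    """
    network.validate()
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be at least 2")
    if not 0 <= ar1_coefficient < 1:
        raise ValueError("ar1_coefficient must lie in [0, 1)")
    n = network.n_regions
    rng = np.random.default_rng(seed)

    coupling = network.weights.copy()
    if subject_jitter_sd > 0:
        upper = np.triu(np.ones((n, n), dtype=bool), k=1)
        j = np.zeros((n, n))
        j[upper] = rng.normal(0.0, subject_jitter_sd, size=int(upper.sum()))
        coupling = coupling + j + j.T

    sigma = _subject_covariance(coupling)
    chol = np.linalg.cholesky(sigma)
    innovations = rng.standard_normal((n_timepoints, n)) @ chol.T
    if ar1_coefficient > 0:
        values = lfilter([1.0], [1.0, -ar1_coefficient], innovations, axis=0)
    else:
        values = innovations
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    ts = RoiTimeSeries(
        subject_id=subject_id,
        group_label=group_label,
        values=values,
        tr_seconds=tr_seconds,
        region_labels=list(network.region_labels),
    )
    ts.validate()
    return ts


def generate_cohort(config: CohortConfig) -> list[RoiTimeSeries]:
    """Generate the full two-group cohort defined by ``config``.

    Group A (label 0) subjects are drawn from the base network; group B
    (label 1) subjects from the effect-injected network. Per-subject seeds
    are derived deterministically from ``config.seed``, so the cohort is
    bit-identical across runs and independent of generation order.
    """
    config.validate()
    labels = default_labels(config.n_regions)
    base = build_group_network(
        config.n_regions,
        config.n_modules,
        config.within_weight,
        config.between_weight,
        config.weight_sd,
        seed=derive_seed(config.seed, 0xBA5E),
        region_labels=labels,
        group_tag="group_a",
    )
    effect = inject_group_effect(base, config.effect_regions, config.effect_multiplier)

    cohort: list[RoiTimeSeries] = []
    for group, net, count in ((0, base, config.n_group_a), (1, effect, config.n_group_b)):
        for i in range(count):
            cohort.append(
                sample_subject_timeseries(
                    net,
                    config.n_timepoints,
                    tr_seconds=config.tr_seconds,
                    subject_jitter_sd=config.subject_jitter_sd,
                    noise_sd=config.noise_sd,
                    ar1_coefficient=config.ar1_coefficient,
                    seed=derive_seed(config.seed, group, i),
                    subject_id=f"sub-{'a' if group == 0 else 'b'}{i + 1:03d}",
                    group_label=group,
                )
            )
    return cohort


def write_cohort(cohort: list[RoiTimeSeries], out_dir: str | Path) -> Path:
    """Write one TSV per subject plus a cohort manifest; returns the manifest path.

    Subject files have a header row of region names and one row per
    timepoint. The manifest lists subject_id, group_label and the file path
    relative to the manifest location.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        fname = f"{ts.subject_id}_timeseries.tsv"
        header = "\t".join(ts.region_labels)
        np.savetxt(out_dir / fname, ts.values, delimiter="\t", header=header, comments="", fmt="%.10g")
        rows.append((ts.subject_id, ts.group_label, fname))
    manifest = out_dir / "cohort_manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject_id\tgroup_label\tpath\n")
        for sid, grp, fname in rows:
            fh.write(f"{sid}\t{grp}\t{fname}\n")
    return manifest
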