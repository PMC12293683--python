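"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a structural-MRI volumetric cohort at the table
level: per-subject total intracranial volume (TIV), per-ROI grey- and
white-matter volumes that decline linearly with age, and a latent
community structure among ROIs — members of the same cluster share a
per-subject factor, inducing the within-cluster covariance the graph
learner is supposed to recover.

Raw volume of ROI i for subject s (in mm^3):

    vol = tiv_s * ( b_i * (1 - k_i * (age_s - age_min))          # atrophy
                    + loading * f_{c(i), s}                      # community
                    + eps )                                      # noise

with b_i a baseline volume fraction, k_i the fractional loss per year,
f ~ N(0,1) per (cluster, subject) and eps ~ N(0, noise_sd). WM is generated
analogously with independent slopes and noise but the same cluster factors,
so both node features carry age signal. Setting slopes and loading to zero
yields a pure-noise null cohort for negative-control experiments.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import ROIVolumeTable, save_volume_table

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort", "edge_recovery_score", "write_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generator settings.

    Defaults describe the study condition used throughout the test-bench:
    400 subjects, 56 ROIs in 4 latent clusters, ages uniform on 51-95
    years, baseline ROI volume fractions of 0.8-2% of TIV, 0.3-0.7% GM
    loss per year, and community/noise terms a factor of ~1.5-2 below the
    age signal so that age is recoverable but not trivially so.
    """

    m_subjects: int = 400
    n_rois: int = 56
    n_clusters: int = 4
    age_range: tuple = (51.0, 95.0)
    baseline_range: tuple = (0.008, 0.020)
    atrophy_slope_range: tuple = (0.003, 0.007)
    wm_slope_range: tuple = (0.002, 0.006)
    latent_loading: float = 6e-4
    noise_sd: float = 4e-4
    tiv_mean: float = 1.5e6
    tiv_sd: float = 1.2e5
    extra_atrophy_years: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.m_subjects < 4 or self.n_rois < 2:
            raise ValueError("need m >= 4 subjects and n >= 2 ROIs")
        if not 1 <= self.n_clusters <= self.n_rois:
            raise ValueError("n_clusters must be in [1, n_rois]")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.tiv_mean <= 0:
            raise ValueError("tiv_mean must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind a generated cohort, for recovery tests."""

    cluster_of_roi: np.ndarray  # (n,) int
    gm_slope: np.ndarray  # (n,) fractional loss / year
    wm_slope: np.ndarray
    baseline: np.ndarray  # (n,) volume fraction of TIV
    factors: np.ndarray  # (n_clusters, m) per-subject community factors

    def to_json(self, path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v) for k, v in payload.items()})


def generate_cohort(config: SyntheticConfig):
    """Draw one cohort; returns ``(ROIVolumeTable, GroundTruth)``.

    The table holds raw volumes in mm^3 (TIV not yet divided out) so it
    exercises the full normalise -> standardise path.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.m_subjects, config.n_rois
    age_min, age_max = config.age_range

    ages = rng.uniform(age_min, age_max, size=m)
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, size=m)
    while np.any(tiv <= 0):  # truncate to positive support
        bad = tiv <= 0
        tiv[bad] = rng.normal(config.tiv_mean, config.tiv_sd, size=int(bad.sum()))

    cluster = rng.integers(0, config.n_clusters, size=n)
    baseline = rng.uniform(*config.baseline_range, size=n)
    gm_slope = rng.uniform(*config.atrophy_slope_range, size=n)
    wm_slope = rng.uniform(*config.wm_slope_range, size=n)
    factors = rng.standard_normal((config.n_clusters, m))

    # effective age includes an optional uniform offset mimicking an
    # accelerated-ageing (elevated brain-age-gap) group
    eff = ages - age_min + config.extra_atrophy_years
    decline_gm = 1.0 - np.outer(eff, gm_slope)  # (m, n)
    decline_wm = 1.0 - np.outer(eff, wm_slope)
    community = config.latent_loading * factors[cluster, :].T  # (m, n)

    gm_frac = baseline * decline_gm + community + rng.normal(0, config.noise_sd, (m, n))
    wm_frac = baseline * decline_wm + community + rng.normal(0, config.noise_sd, (m, n))

    table = ROIVolumeTable(
        subject_ids=tuple(f"S{k:04d}" for k in range(m)),
        ages=ages,
        gm=gm_frac * tiv[:, None],
        wm=wm_frac * tiv[:, None],
        tiv=tiv,
        roi_names=tuple(f"ROI{k:02d}" for k in range(n)),
    )
    truth = GroundTruth(
        cluster_of_roi=cluster,
        gm_slope=gm_slope,
        wm_slope=wm_slope,
        baseline=baseline,
        factors=factors,
    )
    return table, truth


def edge_recovery_score(graph, truth: GroundTruth):
    """Within- vs between-cluster edge densities of a learned graph.

    Returns ``(density_within, density_between, ratio)``; the ratio is NaN
    when the between-cluster density is zero (including the empty graph).
    """
    cluster = np.asarray(truth.cluster_of_roi)
    if graph.n_nodes != len(cluster):
        raise ValueError("graph size does not match ground truth")
    n = graph.n_nodes
    same = cluster[:, None] == cluster[None, :]
    iu = np.triu_indices(n, 1)
    n_within_pairs = int(same[iu].sum())
    n_between_pairs = int((~same[iu]).sum())
    e_within = sum(1 for i, j in graph.edges if cluster[i] == cluster[j])
    e_between = graph.n_edges - e_within
    dw = e_within / n_within_pairs if n_within_pairs else 0.0
    db = e_between / n_between_pairs if n_between_pairs else 0.0
    ratio = dw / db if db > 0 else float("nan")
    return dw, db, ratio


def write_fixture(table: ROIVolumeTable, truth: GroundTruth, directory) -> dict:
    """Persist a cohort as ``cohort.csv`` + ``truth.json``; returns the paths.

    The CSV round-trips losslessly through :func:`brainsage.io.load_volume_table`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table_path = directory / "cohort.csv"
    truth_path = directory / "truth.json"
    save_volume_table(table, table_path)
    truth.to_json(truth_path)
    return {"table": table_path, "truth": truth_path}
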