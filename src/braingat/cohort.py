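"""Seeded synthetic BOLD cohorts with planted group differences.

The generator emulates the shape of a multi-site pediatric resting-state
cohort: ``2 * n_subjects_per_group`` subjects, each an ROI x time matrix of
blood-oxygen-level-dependent (BOLD) signal.  Group 1 (the positive class,
label 1) carries two planted effects confined to a chosen ROI subset:

* a shared latent signal (Gaussian AR(1), lag-1 coefficient 0.3, unit marginal
  variance) mixed into every planted ROI with coupling ``connectivity_effect``
  (lambda), which raises pairwise Pearson correlations among planted ROIs to
  about ``lambda^2 * (1 + a^2/2 ... )`` over total variance — with noise
  standard deviation ``s`` and oscillation amplitude ``a`` the planted-pair
  population correlation is ``(lambda^2 + a^2/2) / (lambda^2 + a^2/2 + s^2)``;
* a slow sinusoid of amplitude ``spectral_effect`` (a) and a fixed period,
  with a random per-subject phase, added to the planted ROIs so their spectral
  content (hence their wavelet features) differs between groups.

Group 0 subjects and all non-planted ROIs are independent Gaussian noise.
Both the correlation structure (the adjacency) and the per-ROI signal
statistics (the node features) therefore carry class signal, which is what a
graph classifier consuming both must be tested against.

Per-subject random substreams are spawned from the cohort seed by subject
index, so generating a cohort is order-independent and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticCohortSpec", "BoldTimeSeries", "generate_subject",
           "generate_cohort", "subject_rng"]

#: lag-1 coefficient of the shared latent AR(1) process
AR_COEFF = 0.3

_SITE_TAGS = ("siteA", "siteB", "siteC", "siteD", "siteE")


@dataclass(frozen=True)
class BoldTimeSeries:
    """One subject's ROI time series: ``values`` is T x N_roi."""

    values: np.ndarray
    subject_id: str
    label: int | None = None
    site: str = "siteA"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (time x ROI) matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"subject {self.subject_id}: non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a planted-effect synthetic cohort.

    Defaults are the strong-effect study condition used throughout the test
    suite: 100 subjects, 200 ROIs, 128 time points, five planted ROIs with
    coupling 0.9 and an oscillation of amplitude 1.0 every 32 time points on
    a noise floor of sd 0.5.
    """

    n_subjects_per_group: int = 50
    n_roi: int = 200
    n_timepoints: int = 128
    planted_rois: tuple[int, ...] = (20, 60, 100, 140, 180)
    connectivity_effect: float = 0.9
    spectral_effect: float = 1.0
    oscillation_period: int = 32
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_rois",
                           tuple(int(r) for r in self.planted_rois))
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if self.n_roi < 1:
            raise ValueError("n_roi must be >= 1")
        if self.n_timepoints < 64:
            raise ValueError(
                "n_timepoints must be >= 64 (a 6-level dyadic wavelet "
                "decomposition needs at least 64 samples)")
        if any(r < 0 or r >= self.n_roi for r in self.planted_rois):
            raise ValueError("planted_rois must be indices in [0, n_roi)")
        if len(set(self.planted_rois)) != len(self.planted_rois):
            raise ValueError("planted_rois contains duplicates")
        has_effect = self.connectivity_effect > 0 or self.spectral_effect > 0
        if has_effect and not self.planted_rois:
            raise ValueError("planted_rois must be non-empty when an effect is set")
        if not 0.0 <= self.connectivity_effect <= 1.0:
            raise ValueError("connectivity_effect (lambda) must lie in [0, 1]")
        if self.spectral_effect < 0:
            raise ValueError("spectral_effect (amplitude) must be >= 0")
        if self.oscillation_period < 2:
            raise ValueError("oscillation_period must be >= 2 time points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_sd == 0 and not (has_effect and self.planted_rois):
            raise ValueError(
                "noise_sd = 0 with no planted effect would produce "
                "zero-variance columns")


def subject_rng(spec: SyntheticCohortSpec, group: int, index: int) -> np.random.Generator:
    """Counter-based per-subject substream: independent of generation order."""
    ss = np.random.SeedSequence(spec.seed, spawn_key=(group, index))
    return np.random.default_rng(ss)


def _ar1_latent(rng: np.random.Generator, n: int) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance and coefficient AR_COEFF."""
    innov_sd = math.sqrt(1.0 - AR_COEFF ** 2)
    eps = rng.normal(0.0, innov_sd, size=n)
    latent = np.empty(n)
    latent[0] = rng.normal()
    for t in range(1, n):
        latent[t] = AR_COEFF * latent[t - 1] + eps[t]
    return latent


def generate_subject(spec: SyntheticCohortSpec, group: int,
                     rng: np.random.Generator,
                     subject_id: str = "sub-000",
                     site: str = "siteA") -> BoldTimeSeries:
    """Draw one subject.

    Non-planted ROIs are i.i.d. Gaussian noise in both groups.  In group 1
    every planted ROI additionally receives ``lambda * latent + a * sin``
    with a subject-specific phase; in group 0 planted ROIs are plain noise.
    """
    if group not in (0, 1):
        raise ValueError("group must be 0 or 1")
    T, N = spec.n_timepoints, spec.n_roi
    values = rng.normal(0.0, spec.noise_sd, size=(T, N))
    if group == 1 and spec.planted_rois:
        common = np.zeros(T)
        if spec.connectivity_effect > 0:
            common += spec.connectivity_effect * _ar1_latent(rng, T)
        if spec.spectral_effect > 0:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            t = np.arange(T)
            common += spec.spectral_effect * np.sin(
                2.0 * math.pi * t / spec.oscillation_period + phase)
        values[:, list(spec.planted_rois)] += common[:, None]
    return BoldTimeSeries(values=values, subject_id=subject_id,
                          label=group, site=site)


def generate_cohort(spec: SyntheticCohortSpec,
                    out_dir: str | Path | None = None) -> list[BoldTimeSeries]:
    """Generate the full balanced cohort (group 0 first, then group 1).

    When ``out_dir`` is given, each subject is written as a TSV
    (T rows x N_roi columns, header ``roi_0001 ...``) together with a
    ``manifest.csv`` listing subject_id, path, label and site.
    """
    subjects: list[BoldTimeSeries] = []
    for group in (0, 1):
        for i in range(spec.n_subjects_per_group):
            sid = f"sub-g{group}-{i:03d}"
            site = _SITE_TAGS[i % len(_SITE_TAGS)]
            rng = subject_rng(spec, group, i)
            subjects.append(generate_subject(spec, group, rng,
                                             subject_id=sid, site=site))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = [f"roi_{i + 1:04d}" for i in range(spec.n_roi)]
        rows = []
        for s in subjects:
            path = out_dir / f"{s.subject_id}.tsv"
            pd.DataFrame(s.values, columns=header).to_csv(
                path, sep="\t", index=False, float_format="%.10g")
            rows.append({"subject_id": s.subject_id, "path": str(path),
                         "label": s.label, "site": s.site})
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return subjects
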