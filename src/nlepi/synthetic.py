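"""Synthetic expression matrices and qPCR CT tables with planted effects.

The generator emulates the statistical structure the downstream analysis
assumes: MAS5-like linear-scale intensities for three sample groups
(RM usual-risk controls, HN tumour-adjacent normal epithelium, PM high-risk
prophylactic-mastectomy tissue), lognormal (or gamma) within-group variation,
a planted subset of differentially expressed probe sets with fold changes in
a configurable range, Present/Marginal/Absent detection calls, and CT tables
whose group dCT differences encode planted fold changes exactly.

Defaults mirror the study design: 18 RM vs 18 HN vs 6 PM samples, planted
folds spanning 2-6x with roughly two thirds of effects higher in RM, and PM
samples whose planted expression copies the HN side of each contrast.
Intensities are emitted *unscaled*; rescaling to mean 200 is the job of the
preprocessing stage, exactly as with raw condensed chip output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .io_formats import CtTable, ExpressionMatrix

Family = Literal["lognormal", "gamma"]
DetectionMode = Literal["independent", "intensity-linked"]


@dataclass
class SimulationConfig:
    """Knobs of the expression simulator.

    ``cv`` is the within-group coefficient of variation of intensities (the
    study never characterises this; 0.2 is a typical condensed-chip value).
    ``fold_range`` bounds the planted linear fold changes; ``frac_up_in_rm``
    is the fraction of planted effects oriented higher-in-RM (2/3, matching
    the observed 66/32 direction split). ``pm_mimics_hn`` makes the planted
    PM expression copy HN, so RM:PM folds equal RM:HN folds.
    """

    n_probes: int = 2000
    n_rm: int = 18
    n_hn: int = 18
    n_pm: int = 6
    n_de: int = 98
    fold_range: tuple[float, float] = (2.0, 6.0)
    frac_up_in_rm: float = 66 / 98
    cv: float = 0.2
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.2
    frac_unexpressed: float = 0.42
    detect_prob_expressed: float = 0.9
    detect_prob_unexpressed: float = 0.05
    pm_mimics_hn: bool = True
    family: Family = "lognormal"
    detection_mode: DetectionMode = "independent"
    seed: int = 0

    def validate(self) -> None:
        if self.n_de > self.n_probes:
            raise ValueError("n_de exceeds n_probes")
        if self.n_de > 0 and self.fold_range[0] <= 1:
            raise ValueError("fold_range lower bound must exceed 1")
        if self.fold_range[1] < self.fold_range[0]:
            raise ValueError("fold_range upper bound below lower bound")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        for name, n in (("n_rm", self.n_rm), ("n_hn", self.n_hn), ("n_pm", self.n_pm)):
            if 0 < n < 2:
                raise ValueError(
                    f"{name}={n}: groups need >=2 samples for variance estimation"
                )
        if self.n_rm < 2 or self.n_hn < 2:
            raise ValueError("RM and HN groups need >=2 samples each")
        if not 0 <= self.frac_unexpressed <= 1:
            raise ValueError("frac_unexpressed must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted-effect oracle paired with a generated matrix.

    ``fold_rm_hn`` / ``fold_rm_pm`` hold the planted linear fold per probe in
    reference-on-the-right orientation (fold > 1 means higher in RM);
    non-differential probes have fold exactly 1.
    """

    de_probe_ids: list[str]
    fold_rm_hn: pd.Series
    fold_rm_pm: pd.Series
    groups: pd.Series
    expressed: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not set(self.de_probe_ids) <= set(self.fold_rm_hn.index):
            raise ValueError("de_probe_ids not a subset of probe ids")
        non_de = self.fold_rm_hn.drop(self.de_probe_ids)
        if not np.allclose(non_de, 1.0):
            raise ValueError("non-differential probes must have planted fold 1")


def _log_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_intensities(
    rng: np.random.Generator, means: np.ndarray, cv: float, family: Family
) -> np.ndarray:
    """Draw positive intensities with the given means and CV, row-wise."""
    if family == "lognormal":
        sigma = _log_sigma(cv)
        mu = np.log(means) - 0.5 * sigma * sigma
        return np.exp(rng.normal(mu, sigma))
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, means / shape)


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate an (unscaled) expression matrix plus its planted ground truth.

    Fully reproducible: a single seed drives a splittable generator with one
    stream per stage (probe baselines, planted folds, intensities, detection).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_fold, rng_intens, rng_detect = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    probe_ids = [f"SP{i + 1:05d}" for i in range(config.n_probes)]
    sample_ids = (
        [f"RM{i + 1:02d}" for i in range(config.n_rm)]
        + [f"HN{i + 1:02d}" for i in range(config.n_hn)]
        + [f"PM{i + 1:02d}" for i in range(config.n_pm)]
    )
    groups = pd.Series(
        ["RM"] * config.n_rm + ["HN"] * config.n_hn + ["PM"] * config.n_pm,
        index=sample_ids,
    )

    n_unexpressed = int(round(config.frac_unexpressed * config.n_probes))
    expressed = np.ones(config.n_probes, dtype=bool)
    if n_unexpressed:
        expressed[rng_base.choice(config.n_probes, n_unexpressed, replace=False)] = False
    baselines = rng_base.normal(
        config.baseline_log_mean, config.baseline_log_sd, config.n_probes
    )
    # unexpressed probe sets sit well below the expressed intensity range
    baselines[~expressed] -= 2.5

    expressed_idx = np.flatnonzero(expressed)
    if config.n_de > len(expressed_idx):
        raise ValueError("n_de exceeds the number of expressed probes")
    de_idx = np.sort(rng_fold.choice(expressed_idx, config.n_de, replace=False))
    lo, hi = np.log(config.fold_range)
    magnitudes = np.exp(rng_fold.uniform(lo, hi, config.n_de))
    up_in_rm = rng_fold.random(config.n_de) < config.frac_up_in_rm
    fold_rm_hn = np.ones(config.n_probes)
    fold_rm_hn[de_idx] = np.where(up_in_rm, magnitudes, 1.0 / magnitudes)
    fold_rm_pm = fold_rm_hn.copy() if config.pm_mimics_hn else np.ones(config.n_probes)

    # per-group mean intensities: HN carries the baseline, RM the planted shift,
    # PM either copies HN (mimicry) or RM.
    mean_hn = np.exp(baselines)
    mean_rm = mean_hn * fold_rm_hn
    mean_pm = mean_rm / fold_rm_pm

    blocks = []
    for mean, n in ((mean_rm, config.n_rm), (mean_hn, config.n_hn), (mean_pm, config.n_pm)):
        if n:
            blocks.append(
                _draw_intensities(
                    rng_intens, np.repeat(mean[:, None], n, axis=1), config.cv, config.family
                )
            )
    intensities = pd.DataFrame(np.hstack(blocks), index=probe_ids, columns=sample_ids)

    n_samples = len(sample_ids)
    p_detect = np.where(
        expressed, config.detect_prob_expressed, config.detect_prob_unexpressed
    )
    present = rng_detect.random((config.n_probes, n_samples)) < p_detect[:, None]
    if config.detection_mode == "intensity-linked":
        # tie Absent calls to the dimmest decile of each sample
        dim = intensities.to_numpy() <= np.quantile(
            intensities.to_numpy(), 0.1, axis=0, keepdims=True
        )
        present &= ~dim
    detection = pd.DataFrame(
        np.where(present, "P", "A"), index=probe_ids, columns=sample_ids
    )

    matrix = ExpressionMatrix(intensities, detection, groups)
    truth = GroundTruth(
        de_probe_ids=[probe_ids[i] for i in de_idx],
        fold_rm_hn=pd.Series(fold_rm_hn, index=probe_ids),
        fold_rm_pm=pd.Series(fold_rm_pm, index=probe_ids),
        groups=groups,
        expressed=pd.Series(expressed, index=probe_ids),
    )
    return matrix, truth


def generate_ct_table(
    folds: Mapping[str, float],
    groups: pd.Series,
    efficiency_noise_sd: float = 0.2,
    seed: int = 0,
    reference_group: str = "RM",
    reference_gene: str = "CPSF6",
    base_ct: float = 22.0,
) -> CtTable:
    """Generate a CT table whose group dCT gaps encode planted fold changes.

    ``folds[gene]`` is the planted expression of each *test* group relative to
    the ``reference_group`` (fold > 1 means the test group expresses more, so
    the recovered 2^-ddCT equals the planted fold). The reference gene has
    planted fold 1 by construction. Per-sample loading offsets are added to
    every CT (they cancel in dCT); Gaussian noise of sd
    ``efficiency_noise_sd`` perturbs each test-gene CT, so the per-sample dCT
    noise sd equals ``efficiency_noise_sd`` exactly.
    """
    if reference_gene in folds:
        raise ValueError("reference gene cannot carry a planted fold")
    for gene, fold in folds.items():
        if not np.isfinite(fold) or fold <= 0:
            raise ValueError(f"unknown or invalid planted fold for gene {gene!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sample_ids = list(groups.index)
    offsets = rng.normal(0.0, 0.5, len(sample_ids))
    rows = []
    for sample, offset in zip(sample_ids, offsets):
        rows.append(
            {
                "sample_id": sample,
                "group": groups[sample],
                "gene": reference_gene,
                "ct": base_ct + offset,
            }
        )
        for gene, fold in folds.items():
            expr = 1.0 if groups[sample] == reference_group else fold
            noise = rng.normal(0.0, efficiency_noise_sd) if efficiency_noise_sd else 0.0
            rows.append(
                {
                    "sample_id": sample,
                    "group": groups[sample],
                    "gene": gene,
                    # CT drops by one cycle per doubling of template
                    "ct": base_ct + 3.0 + offset - np.log2(expr) + noise,
                }
            )
    return CtTable(pd.DataFrame(rows), reference_gene=reference_gene)
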