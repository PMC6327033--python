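"""Synthetic paired reference/validation cohorts with planted contig signal.

The generator emulates the study design downstream stages are tested on: a
reference herd of 30 cows split 15/15 into HIGH/LOW feed-efficiency groups and
an independent validation herd of 31 cows, profiled on a shared contig
universe.  Counts are compositional and overdispersed: each animal has a
latent log-normal relative-intensity profile over contigs, intensities are
perturbed by gamma multipliers (giving Dirichlet-multinomial-like
overdispersion), and the library of each animal is drawn multinomially so raw
counts sum exactly to the sampled library size.

A chosen set of informative contigs has its log-intensity shifted between the
latent HIGH/LOW classes by ±effect_size standard deviations of the baseline
log-intensity noise.  Phenotypes are generated so FE (milk/DMI) tracks the
latent FE class with enough noise that the extreme-group assignment agrees
with the latent class about 90% of the time — groups in such studies are
phenotype-derived, not noiseless.  In the validation herd the contig baselines
are re-drawn (a different diet/environment) and only ``shared_fraction`` of
the informative contigs keep their effect; a configurable fraction of contigs
fails to map across populations at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .core_io import GROUP_HIGH, GROUP_LOW, AbundanceMatrix, DataError, PhenotypeTable

logger = logging.getLogger("rumengwas")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohorts.

    effect_size is the standardized mean shift of an informative contig's
    log-intensity between the latent HIGH and LOW classes, in units of the
    baseline log-intensity SD.  dispersion is the gamma-multiplier
    overdispersion (variance of the multiplicative noise; 0 = multinomial).
    """

    n_ref: int = 30
    n_val: int = 31
    n_contigs: int = 2000
    n_informative: int = 50
    effect_size: float = 1.5
    shared_fraction: float = 0.6
    dispersion: float = 0.3
    library_size_range: tuple = (200_000, 500_000)
    rng_seed: int = 0
    # secondary, intake-linked signal for the parallel DMI analyses
    n_informative_dmi: int = 50
    dmi_effect_size: float = 1.5
    # fraction of contigs mappable in the validation population
    mapped_fraction: float = 0.85
    # baseline model
    log_mean_mu: float = 1.0
    log_mean_sd: float = 1.5
    log_noise_sd: float = 0.5
    env_shift_sd: float = 0.3
    # phenotype model: FE separation/noise tuned for ~90% group/class agreement
    fe_base: float = 1.25
    fe_class_delta: float = 0.16
    fe_noise_sd: float = 0.0625
    dmi_base: float = 20.0
    dmi_class_delta: float = 2.0
    dmi_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_informative + self.n_informative_dmi > self.n_contigs:
            raise DataError("more informative contigs than contigs")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise DataError("shared_fraction must be in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise DataError("effect_size must be finite")
        if self.dispersion < 0:
            raise DataError("dispersion must be >= 0")
        lo, hi = self.library_size_range
        if lo < 10 * self.n_contigs:
            raise DataError("library size too small for the number of contigs "
                            f"(min {lo} < 10 * {self.n_contigs})")
        if lo > hi:
            raise DataError("library_size_range must be (min, max) with min <= max")


@dataclass
class SimulationTruth:
    """Ground truth of the planted signal, for recovery tests."""

    informative_ids: list
    effect_signs: pd.Series            # contig id -> +1/-1
    shared_flags: pd.Series            # contig id -> bool (effect persists in validation)
    informative_dmi_ids: list
    dmi_effect_signs: pd.Series
    phenotype_coefficients: dict       # generative phenotype model parameters

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature_id": f, "trait": "fe", "effect_sign": int(self.effect_signs[f]),
                 "shared": bool(self.shared_flags[f])} for f in self.informative_ids]
        rows += [{"feature_id": f, "trait": "dmi", "effect_sign": int(self.dmi_effect_signs[f]),
                  "shared": True} for f in self.informative_dmi_ids]
        return pd.DataFrame(rows)


def total_log_sd(cfg: SimulationConfig) -> float:
    """SD of a contig's per-animal log-intensity, Gaussian noise plus log-gamma.

    effect_size is defined against this total, so the planted shift is a
    standardized shift on the full log-abundance scale.  The log of a
    Gamma(1/d, d) multiplier has variance trigamma(1/d).
    """
    var = cfg.log_noise_sd ** 2
    if cfg.dispersion > 0:
        var += float(polygamma(1, 1.0 / cfg.dispersion))
    return float(np.sqrt(var))


def _draw_counts(log_intensity: np.ndarray, lib_sizes: np.ndarray,
                 dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Multinomial counts from gamma-perturbed intensities; rows sum to lib size."""
    n, p = log_intensity.shape
    intensity = np.exp(log_intensity)
    if dispersion > 0:
        shape = 1.0 / dispersion
        intensity = intensity * rng.gamma(shape, scale=dispersion, size=(n, p))
    probs = intensity / intensity.sum(axis=1, keepdims=True)
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(int(lib_sizes[i]), probs[i])
    return counts


def _cohort_counts(cfg: SimulationConfig, mu: np.ndarray, latent_fe: np.ndarray,
                   latent_dmi: np.ndarray, fe_shift: np.ndarray,
                   dmi_shift: np.ndarray, sample_ids, feature_ids,
                   rng: np.random.Generator) -> AbundanceMatrix:
    n = len(sample_ids)
    log_int = (mu[None, :]
               + 0.5 * np.outer(latent_fe, fe_shift)
               + 0.5 * np.outer(latent_dmi, dmi_shift)
               + rng.normal(0.0, cfg.log_noise_sd, size=(n, cfg.n_contigs)))
    lo, hi = cfg.library_size_range
    lib = rng.integers(lo, hi + 1, size=n)
    counts = _draw_counts(log_int, lib, cfg.dispersion, rng)
    df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                      columns=feature_ids)
    return AbundanceMatrix(df.astype(float), unit="counts")


def _phenotypes(cfg: SimulationConfig, latent_fe: np.ndarray, latent_dmi: np.ndarray,
                animal_ids, population: str, rng: np.random.Generator) -> PhenotypeTable:
    n = len(animal_ids)
    fe = cfg.fe_base + 0.5 * cfg.fe_class_delta * latent_fe \
        + rng.normal(0.0, cfg.fe_noise_sd, size=n)
    fe = np.clip(fe, 0.05, None)
    dmi = cfg.dmi_base + 0.5 * cfg.dmi_class_delta * latent_dmi \
        + rng.normal(0.0, cfg.dmi_noise_sd, size=n)
    milk = fe * dmi
    bw = rng.normal(650.0, 40.0, size=n)
    parity = rng.choice(["primiparous", "multiparous"], size=n)
    df = pd.DataFrame({
        "animal_id": animal_ids,
        "milk_yield": milk,
        "dmi": dmi,
        "fat_pct": rng.normal(3.8, 0.3, size=n),
        "protein_pct": rng.normal(3.3, 0.2, size=n),
        "body_weight": bw,
        "parity": parity,
        "population": population,
    })
    df["latent_class"] = np.where(latent_fe > 0, GROUP_HIGH, GROUP_LOW)
    df["latent_class_dmi"] = np.where(latent_dmi > 0, GROUP_HIGH, GROUP_LOW)
    return PhenotypeTable(df)


def simulate_cohorts(cfg: SimulationConfig) -> tuple[tuple[AbundanceMatrix, PhenotypeTable],
                                                     tuple[AbundanceMatrix, PhenotypeTable],
                                                     SimulationTruth]:
    """Generate (reference, validation) cohorts plus the planted-signal truth.

    Fully reproducible from ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    feature_ids = [f"contig_{j:05d}" for j in range(cfg.n_contigs)]

    mu_ref = rng.normal(cfg.log_mean_mu, cfg.log_mean_sd, size=cfg.n_contigs)
    pick = rng.choice(cfg.n_contigs, size=cfg.n_informative + cfg.n_informative_dmi,
                      replace=False)
    info_idx = pick[: cfg.n_informative]
    info_dmi_idx = pick[cfg.n_informative:]
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    dmi_signs = rng.choice([-1.0, 1.0], size=cfg.n_informative_dmi)

    sd_total = total_log_sd(cfg)
    fe_shift = np.zeros(cfg.n_contigs)
    fe_shift[info_idx] = signs * cfg.effect_size * sd_total
    dmi_shift = np.zeros(cfg.n_contigs)
    dmi_shift[info_dmi_idx] = dmi_signs * cfg.dmi_effect_size * sd_total

    # latent classes: balanced HIGH/LOW for FE; independent split for DMI
    latent_fe_ref = np.where(rng.permutation(cfg.n_ref) < cfg.n_ref // 2, 1.0, -1.0)
    latent_dmi_ref = np.where(rng.permutation(cfg.n_ref) < cfg.n_ref // 2, 1.0, -1.0)
    ref_ids = [f"ref_{i:03d}" for i in range(cfg.n_ref)]
    ref_m = _cohort_counts(cfg, mu_ref, latent_fe_ref, latent_dmi_ref,
                           fe_shift, dmi_shift, ref_ids, feature_ids, rng)
    ref_p = _phenotypes(cfg, latent_fe_ref, latent_dmi_ref, ref_ids, "reference", rng)

    # validation: re-drawn environment baseline, only shared effects persist
    n_shared = int(round(cfg.shared_fraction * cfg.n_informative))
    shared = np.zeros(cfg.n_informative, dtype=bool)
    shared[rng.choice(cfg.n_informative, size=n_shared, replace=False)] = True
    fe_shift_val = np.zeros(cfg.n_contigs)
    fe_shift_val[info_idx[shared]] = signs[shared] * cfg.effect_size * sd_total
    mu_val = mu_ref + rng.normal(0.0, cfg.env_shift_sd, size=cfg.n_contigs)
    latent_fe_val = np.where(rng.permutation(cfg.n_val) < cfg.n_val // 2, 1.0, -1.0)
    latent_dmi_val = np.where(rng.permutation(cfg.n_val) < cfg.n_val // 2, 1.0, -1.0)
    val_ids = [f"val_{i:03d}" for i in range(cfg.n_val)]
    val_m = _cohort_counts(cfg, mu_val, latent_fe_val, latent_dmi_val,
                           fe_shift_val, dmi_shift, val_ids, feature_ids, rng)
    val_p = _phenotypes(cfg, latent_fe_val, latent_dmi_val, val_ids, "validation", rng)
    if cfg.mapped_fraction < 1.0:
        n_mapped = int(round(cfg.mapped_fraction * cfg.n_contigs))
        mapped = np.sort(rng.choice(cfg.n_contigs, size=n_mapped, replace=False))
        val_m = AbundanceMatrix(val_m.data.iloc[:, mapped], unit="counts")

    truth = SimulationTruth(
        informative_ids=[feature_ids[j] for j in info_idx],
        effect_signs=pd.Series(signs, index=[feature_ids[j] for j in info_idx]),
        shared_flags=pd.Series(shared, index=[feature_ids[j] for j in info_idx]),
        informative_dmi_ids=[feature_ids[j] for j in info_dmi_idx],
        dmi_effect_signs=pd.Series(dmi_signs, index=[feature_ids[j] for j in info_dmi_idx]),
        phenotype_coefficients={
            "fe_base": cfg.fe_base, "fe_class_delta": cfg.fe_class_delta,
            "fe_noise_sd": cfg.fe_noise_sd, "dmi_base": cfg.dmi_base,
            "dmi_class_delta": cfg.dmi_class_delta, "dmi_noise_sd": cfg.dmi_noise_sd,
        },
    )
    return (ref_m, ref_p), (val_m, val_p), truth


def summarize_simulation(ref: tuple, val: tuple, truth: SimulationTruth) -> str:
    """Plain-text report: group sizes, sparsity, library sizes, realized effects."""
    ref_m, ref_p = ref
    val_m, val_p = val
    lines = ["synthetic cohort summary", "========================"]
    latent = ref_p.data["latent_class"]
    lines.append(f"reference animals: {len(ref_p)} "
                 f"({(latent == GROUP_HIGH).sum()} HIGH / {(latent == GROUP_LOW).sum()} LOW latent class)")
    lines.append(f"validation animals: {len(val_p)}")
    lines.append(f"contigs: {ref_m.n_features} (reference), {val_m.n_features} mapped in validation")
    lines.append(f"planted informative contigs: {len(truth.informative_ids)} "
                 f"({int(truth.shared_flags.sum())} shared with validation)"
                 if truth.informative_ids else "planted informative contigs: 0")
    if truth.informative_dmi_ids:
        lines.append(f"planted intake-linked contigs: {len(truth.informative_dmi_ids)}")
    for name, m in (("reference", ref_m), ("validation", val_m)):
        v = m.values
        lib = v.sum(axis=1)
        lines.append(f"{name} sparsity: {np.mean(v == 0):.3f}; "
                     f"library size {lib.min():.0f}-{lib.max():.0f} (median {np.median(lib):.0f})")
    if truth.informative_ids:
        # realized standardized group-mean separation on CPM, reference cohort
        cpm = ref_m.values / ref_m.values.sum(axis=1, keepdims=True) * 1e6
        cols = {f: i for i, f in enumerate(ref_m.feature_ids)}
        hi = (latent == GROUP_HIGH).to_numpy()
        seps = []
        for f in truth.informative_ids:
            x = cpm[:, cols[f]]
            sd = x.std(ddof=0)
            if sd > 0:
                seps.append(abs(x[hi].mean() - x[~hi].mean()) / sd)
        if seps:
            lines.append(f"realized |standardized CPM separation| on planted contigs: "
                         f"median {np.median(seps):.2f}")
    return "\n".join(lines)


def write_truth_csv(truth: SimulationTruth, path) -> None:
    truth.to_frame().to_csv(path, index=False)
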