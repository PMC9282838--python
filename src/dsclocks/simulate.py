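"""Synthetic newborn-cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated closed-loop:

* a two-group cohort (DS / non-DS) whose covariate distributions reproduce the
  study's summary moments (gestational age, age at blood collection in hours,
  birthweight, sex, ALL status, batch, ancestry PCs);
* clock CpGs carrying an exact linear chronological-age signal plus a DS
  offset (and a VAF-proportional offset in GATA1-mutant DS newborns), embedded
  so that applying the clock recovers the true epigenetic age to machine
  precision at zero noise;
* deconvolution CpGs that are reference mixtures of seven cell types by the
  true proportions, with a high-nRBC DS subset;
* chromosome-21 intensity bins shifted by ``attenuation * log2((2 + f)/2)``
  with f = 1 for full trisomy and f = mosaic fraction for mosaics.

Identical (config, seed) pairs produce bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .clocks import (
    TRANSFORM_CALIBRATED,
    TRANSFORM_LINEAR_DAYS,
    ClockDefinition,
    forward_age_transform,
)
from .containers import BetaMatrix, clip_betas
from .deconvolution import CELL_TYPES, CellReference
from .errors import ConfigurationError, ValidationError

AUTOSOMES = tuple(str(c) for c in range(1, 23))
AUTOSOMES_NO21 = tuple(c for c in AUTOSOMES if c != "21")

# Baseline simplex composition of newborn blood (order = CELL_TYPES).
_ALPHA_NON_DS = np.array([0.07, 0.16, 0.09, 0.04, 0.08, 0.50, 0.06])
_ALPHA_DS = np.array([0.05, 0.13, 0.12, 0.07, 0.06, 0.44, 0.13])
_DIRICHLET_CONCENTRATION = 60.0


@dataclass
class SimulationConfig:
    """Cohort-level parameters; defaults reproduce the study's Table-1 moments.

    Collection age is in hours (chronological age in days = GA + hours/24);
    clock-scale quantities are in years.
    """

    n_ds: int = 346
    n_non_ds: int = 567
    ds_clock_offset_years: float = 0.24
    slope_years_per_day: float = 0.001
    baseline_clock_years: float = -0.676  # non-DS mean clock ~ -0.40 at mean age
    ga_mean_sd_ds: tuple = (266.98, 17.65)
    ga_mean_sd_non_ds: tuple = (274.47, 13.93)
    collection_age_mean_sd_ds: tuple = (55.25, 49.74)      # hours
    collection_age_mean_sd_non_ds: tuple = (32.72, 17.46)  # hours
    birthweight_mean_sd_ds: tuple = (3029.90, 686.27)
    birthweight_mean_sd_non_ds: tuple = (3386.10, 541.77)
    male_fraction_ds: float = 0.541
    male_fraction_non_ds: float = 0.584
    all_case_fraction_ds: float = 0.425
    all_case_fraction_non_ds: float = 0.229
    high_nrbc_fraction_ds: float = 0.17
    high_nrbc_fraction_non_ds: float = 0.002
    sequenced_fraction_ds: float = 0.532
    gata1_fraction_ds: float = 0.163          # of sequenced DS
    gata1_vaf_clock_slope: float = 1.78       # years per unit VAF
    gata1_vaf_beta_params: tuple = (0.27, 0.83)  # Table-1 VAF moments over sequenced
    mosaic_fraction_values: tuple = (0.25, 0.30, 0.35, 0.40, 0.45, 0.55)
    noise_sd_beta: float = 0.003
    noise_sd_clock_years: float = 0.07  # clock-scale scatter; non-DS clock SD ~ 0.07
    noise_sd_log2: float = 0.05
    attenuation: float = 0.5
    n_chr21_bins: int = 317
    n_other_bins: int = 100
    n_batches: int = 3
    n_pcs: int = 10
    ga_bounds: tuple = (150.0, 320.0)
    age_missing_fraction: float = 0.0
    missing_beta_fraction: float = 0.0
    allow_cpg_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ds < 1 or self.n_non_ds < 1:
            raise ConfigurationError("need at least one sample per group")
        fracs = {
            "high_nrbc_fraction_ds": self.high_nrbc_fraction_ds,
            "high_nrbc_fraction_non_ds": self.high_nrbc_fraction_non_ds,
            "gata1_fraction_ds": self.gata1_fraction_ds,
            "sequenced_fraction_ds": self.sequenced_fraction_ds,
            "male_fraction_ds": self.male_fraction_ds,
            "male_fraction_non_ds": self.male_fraction_non_ds,
            "all_case_fraction_ds": self.all_case_fraction_ds,
            "all_case_fraction_non_ds": self.all_case_fraction_non_ds,
            "age_missing_fraction": self.age_missing_fraction,
            "missing_beta_fraction": self.missing_beta_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("ga_mean_sd_ds", "ga_mean_sd_non_ds",
                     "collection_age_mean_sd_ds", "collection_age_mean_sd_non_ds",
                     "birthweight_mean_sd_ds", "birthweight_mean_sd_non_ds"):
            if getattr(self, name)[1] < 0:
                raise ConfigurationError(f"{name} has negative SD")
        if not 0.0 < self.attenuation <= 1.0:
            raise ConfigurationError("attenuation must be in (0, 1]")
        for f in self.mosaic_fraction_values:
            if not 0.0 < f < 1.0:
                raise ConfigurationError(f"mosaic fraction {f} outside (0, 1)")
        if min(self.noise_sd_beta, self.noise_sd_log2, self.noise_sd_clock_years) < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        if len(self.mosaic_fraction_values) > self.n_ds:
            raise ConfigurationError("more mosaic fractions than DS samples")


@dataclass
class CohortTruth:
    """Ground truth for recovery tests."""

    epigenetic_age: pd.DataFrame      # clock x sample true targets
    cell_props: pd.DataFrame          # sample x cell type
    t21_class: pd.Series              # 'full' | 'mosaic' | 'none'
    mosaic_fraction: pd.Series        # NaN unless mosaic
    gata1_vaf: pd.Series              # 0 where sequenced negative; NaN unsequenced
    high_nrbc: pd.Series
    ds_clock_offset_years: float
    n_clipped_betas: int = 0

    def to_json(self, path) -> None:
        payload = {
            "epigenetic_age": self.epigenetic_age.to_dict(),
            "cell_props": self.cell_props.to_dict(),
            "t21_class": self.t21_class.to_dict(),
            "mosaic_fraction": {
                k: (None if pd.isna(v) else v) for k, v in self.mosaic_fraction.items()
            },
            "gata1_vaf": {
                k: (None if pd.isna(v) else v) for k, v in self.gata1_vaf.items()
            },
            "high_nrbc": {k: bool(v) for k, v in self.high_nrbc.items()},
            "ds_clock_offset_years": self.ds_clock_offset_years,
            "n_clipped_betas": self.n_clipped_betas,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@lru_cache(maxsize=64)
def _truncnorm_underlying(mean: float, sd: float, low: float, high: float):
    """Location/scale of an untruncated normal whose [low, high]-truncation has
    the requested mean and SD (moment matching)."""
    if sd == 0:
        return mean, 0.0

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (low - mu) / sigma, (high - mu) / sigma
        m, v = scipy.stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ier, _ = scipy.optimize.fsolve(
        moments, [mean, np.log(sd)], full_output=True
    )
    if ier != 1:
        return mean, sd  # fall back to plain clipping parameters
    return float(sol[0]), float(np.exp(sol[1]))


def _draw_truncated(rng, mean, sd, low, high, n):
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = _truncnorm_underlying(float(mean), float(sd), float(low), float(high))
    if sigma == 0:
        return np.full(n, mu)
    a, b = (low - mu) / sigma, (high - mu) / sigma
    u = rng.uniform(size=n)
    return scipy.stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def generate_cell_reference(n_deconv_cpgs: int, seed: int) -> CellReference:
    """Random full-rank 7-cell-type reference with mean betas in [0.05, 0.95]."""
    if n_deconv_cpgs < 7:
        raise ConfigurationError(
            f"need >= 7 reference CpGs for 7 identifiable cell types; got {n_deconv_cpgs}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(20):
        mat = rng.uniform(0.05, 0.95, size=(len(CELL_TYPES), n_deconv_cpgs))
        if np.linalg.matrix_rank(mat) == len(CELL_TYPES):
            break
    cols = pd.Index([f"cgref{seed % 1000:03d}{i:05d}" for i in range(n_deconv_cpgs)],
                    name="cpg_id")
    return CellReference(pd.DataFrame(mat, index=list(CELL_TYPES), columns=cols))


def generate_synthetic_clock(
    n_cpgs: int,
    transform: str = TRANSFORM_CALIBRATED,
    seed: int = 0,
    name: str | None = None,
) -> ClockDefinition:
    """A clock with known weights whose attainable output covers the newborn range.

    Weights are mixed-sign (as published clock coefficients are) and scaled to
    the smallest magnitude at which, starting from betas of 0.5, the linear
    predictor can still be moved far enough within [0, 1]^n to reach any
    target in roughly (-0.95, 2] years (calibrated) or [150, 330] days
    (gestational).  Small weights keep CpG-excluded clock variants
    well-behaved, mirroring real coefficient files.
    """
    if n_cpgs < 1:
        raise ConfigurationError("a clock needs at least one CpG")
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.5, 1.5, size=n_cpgs) * rng.choice([-1.0, 1.0], size=n_cpgs)
    if transform == TRANSFORM_CALIBRATED:
        lp_mid = forward_age_transform(0.3)
        needed = max(abs(forward_age_transform(-0.95) - lp_mid),
                     abs(forward_age_transform(2.0) - lp_mid))
    elif transform == TRANSFORM_LINEAR_DAYS:
        lp_mid = 270.0
        needed = 130.0
    else:
        raise ValidationError(f"unknown transform '{transform}'")
    capacity = 0.5 * float(w @ w) / float(np.abs(w).max())
    w *= 1.2 * needed / capacity  # smallest scale with 20% headroom
    intercept = lp_mid - 0.5 * float(w.sum())
    ids = pd.Index([f"cg{seed % 1000:03d}{i:05d}" for i in range(n_cpgs)], name="cpg_id")
    return ClockDefinition(
        name=name or f"synthetic-{transform}-{seed}",
        intercept=intercept,
        weights=pd.Series(w, index=ids),
        transform=transform,
    )


def embed_age_signal(
    clock: ClockDefinition, targets, rng=None, noise_sd: float = 0.0
) -> tuple[np.ndarray, int]:
    """Betas (CpG x sample) whose clock output equals the given targets.

    The target linear predictor is distributed across CpGs proportionally to
    ``w_j / Σ w_k^2`` around a base beta of 0.5, then optionally perturbed by
    iid Gaussian noise and clipped to [0, 1].  Returns (betas, n_clipped).
    """
    targets = np.asarray(targets, dtype=float)
    w = clock.weights.to_numpy()
    if clock.transform == TRANSFORM_CALIBRATED:
        lp = forward_age_transform(targets, clock.adult_age)
    else:
        lp = targets
    delta = lp - (clock.intercept + 0.5 * float(w.sum()))
    betas = 0.5 + np.outer(w / float(w @ w), delta)
    if noise_sd > 0:
        if rng is None:
            raise ValidationError("noise requested without a random generator")
        betas = betas + rng.normal(0.0, noise_sd, size=betas.shape)
    return clip_betas(betas)


def _mixture_block(reference: CellReference, props: np.ndarray, rng, noise_sd: float):
    """Deconvolution CpG betas: reference mixtures by the true proportions."""
    block = props @ reference.mean_betas.to_numpy()  # sample x CpG
    if noise_sd > 0:
        block = block + rng.normal(0.0, noise_sd, size=block.shape)
    return clip_betas(block.T)  # CpG x sample


def generate_cohort(
    config: SimulationConfig,
    clocks,
    reference: CellReference,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Full synthetic cohort: betas, sample sheet, bin-level log2 table, truth.

    Calibrated (age) clocks carry the DS offset and the GATA1-VAF offset;
    gestational clocks track observed GA only.  Clock and reference CpG sets
    must be pairwise disjoint unless ``config.allow_cpg_overlap``.
    """
    rng = np.random.default_rng(config.seed)
    clocks = list(clocks)

    seen: dict[str, str] = {c: "reference" for c in reference.cpg_ids}
    for clock in clocks:
        for c in clock.cpg_ids:
            if c in seen and not config.allow_cpg_overlap:
                raise ConfigurationError(
                    f"CpG '{c}' shared between clock '{clock.name}' and {seen[c]}; "
                    "set allow_cpg_overlap to permit this"
                )
            seen.setdefault(c, f"clock '{clock.name}'")

    n_ds, n_nd = config.n_ds, config.n_non_ds
    n = n_ds + n_nd
    samples = pd.Index(
        [f"DS{i + 1:04d}" for i in range(n_ds)] + [f"ND{i + 1:04d}" for i in range(n_nd)],
        name="sample_id",
    )
    ds = np.repeat([True, False], [n_ds, n_nd])

    # --- covariates -------------------------------------------------------
    ga = np.concatenate([
        _draw_truncated(rng, *config.ga_mean_sd_ds, *config.ga_bounds, n_ds),
        _draw_truncated(rng, *config.ga_mean_sd_non_ds, *config.ga_bounds, n_nd),
    ])
    coll = np.concatenate([
        _draw_truncated(rng, *config.collection_age_mean_sd_ds, 0.0, np.inf, n_ds),
        _draw_truncated(rng, *config.collection_age_mean_sd_non_ds, 0.0, np.inf, n_nd),
    ])
    bw = np.concatenate([
        rng.normal(*config.birthweight_mean_sd_ds, n_ds),
        rng.normal(*config.birthweight_mean_sd_non_ds, n_nd),
    ])
    male = np.concatenate([
        rng.uniform(size=n_ds) < config.male_fraction_ds,
        rng.uniform(size=n_nd) < config.male_fraction_non_ds,
    ])
    all_status = np.concatenate([
        rng.uniform(size=n_ds) < config.all_case_fraction_ds,
        rng.uniform(size=n_nd) < config.all_case_fraction_non_ds,
    ])
    batch = rng.integers(1, config.n_batches + 1, size=n)
    pcs = rng.normal(size=(n, config.n_pcs))

    # --- GATA1 mutation status within sequenced DS ------------------------
    gata1_status = np.full(n, np.nan)
    gata1_vaf = np.full(n, np.nan)
    sequenced = rng.uniform(size=n_ds) < config.sequenced_fraction_ds
    positive = sequenced & (rng.uniform(size=n_ds) < config.gata1_fraction_ds)
    gata1_status[:n_ds] = np.where(sequenced, positive.astype(float), np.nan)
    vaf_draw = rng.beta(*config.gata1_vaf_beta_params, size=n_ds)
    gata1_vaf[:n_ds] = np.where(sequenced, np.where(positive, vaf_draw, 0.0), np.nan)
    vaf_true = np.nan_to_num(gata1_vaf, nan=0.0)

    # --- cell proportions with high-nRBC and GATA1 structure --------------
    alpha_ds = _ALPHA_DS * _DIRICHLET_CONCENTRATION
    alpha_nd = _ALPHA_NON_DS * _DIRICHLET_CONCENTRATION
    props = np.vstack([
        rng.dirichlet(alpha_ds, size=n_ds),
        rng.dirichlet(alpha_nd, size=n_nd),
    ])
    high = np.concatenate([
        rng.uniform(size=n_ds) < config.high_nrbc_fraction_ds,
        rng.uniform(size=n_nd) < config.high_nrbc_fraction_non_ds,
    ])
    nrbc_col = CELL_TYPES.index("nRBC")
    high_nrbc_draw = rng.uniform(0.26, 0.45, size=n)
    gata1_nrbc_draw = rng.uniform(0.12, 0.30, size=n)
    gata1_pos_full = np.concatenate([positive, np.zeros(n_nd, dtype=bool)])
    for i in range(n):
        target = None
        if high[i]:
            target = high_nrbc_draw[i]
        elif gata1_pos_full[i] and props[i, nrbc_col] < gata1_nrbc_draw[i]:
            target = gata1_nrbc_draw[i]  # confounding: GATA1+ newborns run nRBC-high
        if target is not None:
            rest = np.delete(props[i], nrbc_col)
            rest = rest / rest.sum() * (1.0 - target)
            props[i] = np.insert(rest, nrbc_col, target)

    # --- T21 classes and bin-level dosage signal --------------------------
    t21_class = np.where(ds, "full", "none").astype(object)
    mosaic_fraction = np.full(n, np.nan)
    n_mosaic = len(config.mosaic_fraction_values)
    if n_mosaic:
        mosaic_idx = rng.choice(n_ds, size=n_mosaic, replace=False)
        for idx, f in zip(mosaic_idx, config.mosaic_fraction_values):
            t21_class[idx] = "mosaic"
            mosaic_fraction[idx] = f
    copy_gain = np.where(
        t21_class == "full", 1.0, np.nan_to_num(mosaic_fraction, nan=0.0)
    )
    chr21_shift = config.attenuation * np.log2((2.0 + copy_gain) / 2.0)

    n_bins = config.n_chr21_bins + config.n_other_bins
    log2 = rng.normal(0.0, config.noise_sd_log2, size=(n, n_bins))
    log2[:, :config.n_chr21_bins] += chr21_shift[:, None]
    bins = pd.DataFrame({
        "sample_id": np.repeat(samples.to_numpy(), n_bins),
        "chromosome": np.tile(
            np.array(["21"] * config.n_chr21_bins + ["1"] * config.n_other_bins),
            n,
        ),
        "bin_index": np.tile(
            np.concatenate([np.arange(config.n_chr21_bins),
                            np.arange(config.n_other_bins)]),
            n,
        ),
        "log2_ratio": log2.ravel(),
    })

    # --- true clock targets and beta blocks -------------------------------
    chron = ga + coll / 24.0
    age_target = (
        config.baseline_clock_years
        + config.slope_years_per_day * chron
        + config.ds_clock_offset_years * ds.astype(float)
        + config.gata1_vaf_clock_slope * vaf_true
    )
    truth_rows = {}
    blocks, chroms, n_clipped = [], [], 0
    for clock in clocks:
        if clock.transform == TRANSFORM_CALIBRATED:
            # clock-scale scatter (biology + assay) on top of the linear signal
            targets = age_target + rng.normal(0.0, config.noise_sd_clock_years, size=n) \
                if config.noise_sd_clock_years > 0 else age_target
        else:
            targets = ga
        block, clipped = embed_age_signal(clock, targets, rng, config.noise_sd_beta)
        n_clipped += clipped
        blocks.append(pd.DataFrame(block, index=clock.cpg_ids, columns=samples))
        chroms.append(pd.Series(
            rng.choice(AUTOSOMES, size=len(clock.cpg_ids)), index=clock.cpg_ids
        ))
        truth_rows[clock.name] = targets
    ref_block, clipped = _mixture_block(reference, props, rng, config.noise_sd_beta)
    n_clipped += clipped
    blocks.append(pd.DataFrame(ref_block, index=reference.cpg_ids, columns=samples))
    chroms.append(pd.Series(
        rng.choice(AUTOSOMES_NO21, size=len(reference.cpg_ids)), index=reference.cpg_ids
    ))
    values = pd.concat(blocks)
    chromosome = pd.concat(chroms)
    if config.missing_beta_fraction > 0:
        mask = rng.uniform(size=values.shape) < config.missing_beta_fraction
        values = values.mask(mask)

    betas = BetaMatrix(values, chromosome)

    # --- sample sheet ------------------------------------------------------
    if config.age_missing_fraction > 0:
        drop = rng.uniform(size=n) < config.age_missing_fraction
        ga = np.where(drop, np.nan, ga)
        coll = np.where(drop, np.nan, coll)
        chron = ga + coll / 24.0
    sheet = pd.DataFrame({
        "ds": ds,
        "sex": np.where(male, "M", "F"),
        "ga_days": ga,
        "collection_age_hours": coll,
        "chron_age_days": chron,
        "birthweight_g": bw,
        "batch": [f"B{b}" for b in batch],
        "all_status": all_status,
        "gata1_status": gata1_status,
        "gata1_vaf": gata1_vaf,
    }, index=samples)
    for j in range(config.n_pcs):
        sheet[f"pc{j + 1}"] = pcs[:, j]

    truth = CohortTruth(
        epigenetic_age=pd.DataFrame(truth_rows, index=samples).T,
        cell_props=pd.DataFrame(props, index=samples, columns=list(CELL_TYPES)),
        t21_class=pd.Series(t21_class, index=samples, name="t21_class"),
        mosaic_fraction=pd.Series(mosaic_fraction, index=samples, name="mosaic_fraction"),
        gata1_vaf=pd.Series(gata1_vaf, index=samples, name="gata1_vaf"),
        high_nrbc=pd.Series(high, index=samples, name="high_nrbc"),
        ds_clock_offset_years=config.ds_clock_offset_years,
        n_clipped_betas=n_clipped,
    )
    return betas, sheet, bins, truth


def default_clock_set(seed: int = 0):
    """The five study clocks at their published CpG counts, as synthetic clocks.

    pan-tissue 353, skin & blood 391 (calibrated, years); Haftorn 176,
    Knight 148, Bohlin 96 (linear, days).
    """
    return [
        generate_synthetic_clock(391, TRANSFORM_CALIBRATED, seed + 1, name="skinblood"),
        generate_synthetic_clock(353, TRANSFORM_CALIBRATED, seed + 2, name="pantissue"),
        generate_synthetic_clock(176, TRANSFORM_LINEAR_DAYS, seed + 3, name="haftorn"),
        generate_synthetic_clock(148, TRANSFORM_LINEAR_DAYS, seed + 4, name="knight"),
        generate_synthetic_clock(96, TRANSFORM_LINEAR_DAYS, seed + 5, name="bohlin"),
    ]
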