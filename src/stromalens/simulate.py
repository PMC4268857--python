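"""Synthetic data with known ground truth for every pipeline stage.

Nothing here downloads or imitates real patient data. The generators
produce:

* H&E-like RGB tiles in which tissue is a smooth random blob, a stromal
  subregion of known area fraction is carved out of it, tumour regions are
  rendered haematoxylin-dominant with nuclear speckle and stroma
  eosin-dominant with fibrous texture, all through the forward Beer-Lambert
  stain model;
* two-compartment expression mixtures x = f*s + (1-f)*t + noise in which
  observed PTEN is confounded with stromal content (stromal PTEN is
  constant and positive) while tumour-cell PTEN tracks the gene's copy
  state, and tumour AR is coupled to tumour PTEN;
* staining-category labels drawn from a copy-state-conditional confusion
  matrix; and
* left-truncated survival tables with a configurable true hazard ratio for
  reduced-PTEN cases, realised by the standard delayed-entry scheme of
  conditioning on survival past a uniform entry time.

Every generator is a pure function of (config, seed): regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .segmentation import RUIFROK_HE, StainBasis, od_to_rgb

__all__ = [
    "ImageConfig",
    "CohortConfig",
    "SurvivalConfig",
    "SyntheticTruth",
    "DEFAULT_CONFUSION",
    "generate_he_image",
    "generate_cohort_expression",
    "generate_staining",
    "generate_clinical",
]

COPY_STATES = ("homdel", "hetloss", "diploid")


@dataclass(frozen=True)
class ImageConfig:
    """Forward model for one H&E-like tile."""

    size: int = 128
    basis: StainBasis = RUIFROK_HE
    background_intensity: float = 255.0
    tissue_area: float = 0.72          # fraction of the tile covered by tissue
    tissue_scale: float = 16.0         # px, blob smoothness
    stroma_scale: float = 8.0          # px, stromal-region smoothness
    tumour_h: float = 1.0              # haematoxylin OD concentration in tumour
    tumour_e: float = 0.25
    stroma_h: float = 0.30
    stroma_e: float = 0.90
    nucleus_h: float = 0.9             # extra haematoxylin at nuclear speckles
    nucleus_density: float = 0.10      # fraction of tumour pixels speckled
    texture_amplitude: float = 0.20    # multiplicative concentration jitter
    pixel_noise_sd: float = 1.5        # additive RGB noise, intensity units
    fraction_tolerance: float = 0.02
    max_threshold_iter: int = 50


@dataclass(frozen=True)
class CohortConfig:
    """Two-compartment expression mixture with PTEN copy-state structure."""

    n_samples: int = 300
    n_genes: int = 2000
    n_signature: int = 100             # stromal signature genes incl. ACTA2
    fraction_alpha: float = 2.0        # stromal fraction ~ Beta(alpha, beta)
    fraction_beta: float = 2.0
    noise_sd: float = 0.5              # log2 measurement noise
    tumour_sample_sd: float = 0.3      # per-sample tumour-profile wobble
    signature_stroma_mean: float = 10.0
    signature_tumour_mean: float = 5.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    stromal_pten: float = 9.0          # constant stromal PTEN (log2)
    tumour_pten_base: float = 8.0
    copy_state_probs: tuple = (0.06, 0.36, 0.58)   # homdel, hetloss, diploid
    copy_factors: tuple = (0.1, 0.55, 1.0)         # linear-scale expression factor
    ar_pten_rho: float = 0.4           # tumour AR ~ tumour PTEN coupling
    pten_noise_sd: float = 0.2


@dataclass(frozen=True)
class SurvivalConfig:
    """Left-truncated survival with a marker hazard ratio."""

    baseline_rate: float = 0.012       # events / month, exponential baseline
    hazard_ratio: float = 1.8          # for reduced-PTEN cases
    entry_max: float = 36.0            # entry ~ Uniform(0, entry_max) months
    horizon: float = 120.0             # administrative censoring, months
    max_redraws: int = 10_000


@dataclass
class SyntheticTruth:
    """Ground truth tied to a seed; everything needed to audit the pipeline."""

    seed: int
    fractions: pd.Series               # per-sample stromal fraction f in (0, 1)
    stroma_profile: pd.Series          # per-gene stromal expression s (log2)
    tumour_profiles: pd.DataFrame      # gene x sample tumour expression t (log2)
    copy_state: pd.Series
    signature_genes: tuple
    rho: float
    noise_sd: float
    config: CohortConfig = field(repr=False, default=None)


def _smooth_field(rng, size, scale):
    field_ = gaussian_filter(rng.standard_normal((size, size)), sigma=scale)
    return (field_ - field_.mean()) / (field_.std() + 1e-12)


def generate_he_image(target_fraction: float, config: ImageConfig | None = None,
                      seed: int = 0):
    """One H&E-like tile with a known stromal fraction.

    Returns ``(rgb, tissue_mask, stroma_mask, achieved_fraction)``. The
    stromal threshold on a smooth noise field is iterated (bisection on the
    field quantile) until the achieved fraction of tissue area is within
    ``fraction_tolerance`` of the target.
    """
    cfg = config or ImageConfig()
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    size = cfg.size

    blob = _smooth_field(rng, size, cfg.tissue_scale)
    tissue = blob > np.quantile(blob, 1.0 - cfg.tissue_area)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue_area too small: no tissue generated")

    stroma_field = _smooth_field(rng, size, cfg.stroma_scale)
    if target_fraction <= 0:
        stroma = np.zeros_like(tissue)
    elif target_fraction >= 1:
        stroma = tissue.copy()
    else:
        in_tissue = stroma_field[tissue]
        lo_q, hi_q = 0.0, 1.0
        stroma = None
        for _ in range(cfg.max_threshold_iter):
            q = 0.5 * (lo_q + hi_q) if stroma is not None else 1.0 - target_fraction
            thr = np.quantile(in_tissue, q)
            cand = tissue & (stroma_field > thr)
            achieved = cand.sum() / n_tissue
            if abs(achieved - target_fraction) <= cfg.fraction_tolerance:
                stroma = cand
                break
            if stroma is None:
                lo_q, hi_q = 0.0, 1.0
            if achieved > target_fraction:
                lo_q = q
            else:
                hi_q = q
            stroma = cand
        else:
            raise ValueError(
                f"could not reach stromal fraction {target_fraction} within "
                f"{cfg.max_threshold_iter} threshold iterations")
    achieved = float(stroma.sum() / n_tissue)

    tumour = tissue & ~stroma
    texture = 1.0 + cfg.texture_amplitude * _smooth_field(rng, size, 1.0)
    c_h = np.where(tumour, cfg.tumour_h, np.where(stroma, cfg.stroma_h, 0.0))
    c_e = np.where(tumour, cfg.tumour_e, np.where(stroma, cfg.stroma_e, 0.0))
    # nuclear speckle: the most intense patches of a fine noise field
    nuc_field = gaussian_filter(rng.standard_normal((size, size)), sigma=1.0)
    if tumour.any():
        nuc_thr = np.quantile(nuc_field[tumour], 1.0 - cfg.nucleus_density)
        c_h = c_h + np.where(tumour & (nuc_field > nuc_thr), cfg.nucleus_h, 0.0)
    # fibrous texture in stroma follows an elongated (anisotropic) field
    fibre = gaussian_filter(rng.standard_normal((size, size)), sigma=(0.5, 4.0))
    fibre = (fibre - fibre.mean()) / (fibre.std() + 1e-12)
    c_e = c_e + np.where(stroma, 0.15 * fibre, 0.0)
    c_h = np.clip(c_h * texture, 0.0, None)
    c_e = np.clip(c_e * texture, 0.0, None)

    vectors = cfg.basis.vectors
    od = c_h[..., None] * vectors[0] + c_e[..., None] * vectors[1]
    rgb = cfg.background_intensity * np.power(10.0, -od)
    rgb = rgb + rng.normal(0.0, cfg.pixel_noise_sd, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb, tissue, stroma, achieved


def _gene_ids(cfg: CohortConfig):
    n_sig = cfg.n_signature
    signature = ("ACTA2",) + tuple(f"SIG_{i:04d}" for i in range(1, n_sig))
    n_fill = cfg.n_genes - n_sig - 2    # PTEN and AR on top of the signature
    if n_fill < 0:
        raise ValueError("n_genes too small for the signature plus PTEN and AR")
    filler = tuple(f"GENE_{i:04d}" for i in range(1, n_fill + 1))
    return ("PTEN", "AR") + signature + filler, signature


def generate_cohort_expression(config: CohortConfig | None = None, seed: int = 0):
    """Gene x sample log2 mixture with stroma/PTEN/AR structure.

    ``x_ij = f_j s_i + (1 - f_j) t_ij + eps_ij`` with f ~ Beta(a, b) and
    eps ~ N(0, noise_sd^2). Signature genes (incl. ACTA2) have high stromal
    and low tumour expression. Tumour PTEN is the base level times the
    copy-state factor (log2-additive); stromal PTEN is constant and
    positive, so observed PTEN rises with stromal content even though
    tumour PTEN is independent of it. Tumour AR is correlated (rho) with
    standardised tumour PTEN. Returns ``(expr, truth)``.
    """
    cfg = config or CohortConfig()
    if not np.isclose(sum(cfg.copy_state_probs), 1.0):
        raise ValueError("copy_state_probs must sum to 1")
    rng = np.random.default_rng(seed)
    genes, signature = _gene_ids(cfg)
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    n_g, n_s = len(genes), len(samples)

    f = rng.beta(cfg.fraction_alpha, cfg.fraction_beta, n_s)
    f = np.clip(f, 1e-3, 1 - 1e-3)

    stroma = pd.Series(rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_g),
                       index=genes)
    t_base = pd.Series(rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_g),
                       index=genes)
    stroma[list(signature)] = rng.normal(cfg.signature_stroma_mean, 0.5,
                                         len(signature))
    t_base[list(signature)] = rng.normal(cfg.signature_tumour_mean, 0.5,
                                         len(signature))
    stroma["PTEN"] = cfg.stromal_pten
    stroma["AR"] = 5.0                  # AR is tumour-cell biology, low in stroma
    stroma["ACTA2"] = cfg.signature_stroma_mean + 1.0   # canonical stromal marker
    t_base["ACTA2"] = cfg.signature_tumour_mean - 0.5

    copy_state = pd.Series(
        rng.choice(COPY_STATES, size=n_s, p=cfg.copy_state_probs), index=samples)
    factors = dict(zip(COPY_STATES, cfg.copy_factors))
    t_pten = (cfg.tumour_pten_base
              + np.log2(copy_state.map(factors).to_numpy(dtype=float))
              + rng.normal(0.0, cfg.pten_noise_sd, n_s))
    z_pten = (t_pten - t_pten.mean()) / (t_pten.std() + 1e-12)
    rho = cfg.ar_pten_rho
    t_ar = 8.0 + 1.0 * (rho * z_pten
                        + np.sqrt(1 - rho**2) * rng.standard_normal(n_s))

    t = (t_base.to_numpy()[:, None]
         + rng.normal(0.0, cfg.tumour_sample_sd, (n_g, n_s)))
    gi = pd.Index(genes)
    t[gi.get_loc("PTEN"), :] = t_pten
    t[gi.get_loc("AR"), :] = t_ar

    eps = rng.normal(0.0, cfg.noise_sd, (n_g, n_s))
    x = f[None, :] * stroma.to_numpy()[:, None] + (1 - f[None, :]) * t + eps
    expr = pd.DataFrame(x, index=genes, columns=samples)
    truth = SyntheticTruth(
        seed=seed,
        fractions=pd.Series(f, index=samples, name="stromal_fraction"),
        stroma_profile=stroma,
        tumour_profiles=pd.DataFrame(t, index=genes, columns=samples),
        copy_state=copy_state,
        signature_genes=signature,
        rho=rho,
        noise_sd=cfg.noise_sd,
        config=cfg,
    )
    return expr, truth


#: Default copy-state -> staining-category confusion. Rows sum to 1 and
#: concentrate homozygous deletion on negative staining, hemizygous loss on
#: weak/heterogeneous staining and diploid on positive staining.
DEFAULT_CONFUSION = pd.DataFrame(
    {
        "negative":      [0.80, 0.10, 0.02],
        "weak_positive": [0.10, 0.45, 0.13],
        "heterogeneous": [0.10, 0.35, 0.15],
        "positive":      [0.00, 0.10, 0.70],
    },
    index=list(COPY_STATES),
)


def generate_staining(copy_states, confusion: pd.DataFrame | None = None,
                      seed: int = 0) -> pd.Series:
    """Draw a staining category per sample from its copy state's confusion row."""
    copy_states = pd.Series(copy_states)
    conf = DEFAULT_CONFUSION if confusion is None else confusion
    if not np.allclose(conf.sum(axis=1), 1.0):
        raise ValueError("confusion rows must sum to 1")
    if np.any(conf.to_numpy() < 0):
        raise ValueError("confusion probabilities must be non-negative")
    missing = set(copy_states.unique()) - set(conf.index)
    if missing:
        raise ValueError(f"no confusion row for states {sorted(missing)}")
    rng = np.random.default_rng(seed)
    cats = list(conf.columns)
    out = [rng.choice(cats, p=conf.loc[state].to_numpy(dtype=float))
           for state in copy_states]
    return pd.Series(out, index=copy_states.index, name="staining")


def generate_clinical(reduced_marker, config: SurvivalConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Left-truncated survival table for samples with a reduced-PTEN flag.

    Event times are exponential with hazard ``baseline_rate *
    hazard_ratio^reduced``. Entry times are Uniform(0, entry_max) months
    since diagnosis; (entry, event-time) pairs are redrawn until the
    subject survives past entry — the delayed-entry sampling scheme that
    makes early deaths unobservable. Exit is censored administratively at
    the horizon. Age, stage, grade and site are drawn from simple cohort
    laws and carry no true hazard effect.
    """
    cfg = config or SurvivalConfig()
    if cfg.baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    reduced = pd.Series(reduced_marker).astype(bool)
    rng = np.random.default_rng(seed)
    rows = []
    for sid, red in reduced.items():
        rate = cfg.baseline_rate * (cfg.hazard_ratio if red else 1.0)
        for _ in range(cfg.max_redraws):
            t = rng.exponential(1.0 / rate)
            entry = rng.uniform(0.0, cfg.entry_max)
            if t > entry:
                break
        else:
            raise RuntimeError("could not draw a subject surviving past entry")
        exit_time = min(t, cfg.horizon)
        rows.append({
            "sample_id": sid,
            "entry_time": entry,
            "exit_time": exit_time,
            "event": int(t <= cfg.horizon),
            "pten_reduced": int(red),
            "age": rng.normal(58.0, 8.0),
            "stage": int(rng.choice([1, 2, 3, 4], p=[0.19, 0.11, 0.59, 0.11])),
            "grade": int(rng.choice([1, 2, 3], p=[0.0, 0.28, 0.72])),
            "site": str(rng.choice(["site_A", "site_B"])),
        })
    return pd.DataFrame(rows).set_index("sample_id")
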