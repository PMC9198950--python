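"""Synthetic flow-cytometry screen generator.

Per-well eGFP intensity profiles are drawn from a four-component mixture of
log10-normal subpopulations (reporter-negative, Dim, Mid, Bright).  A gene
knockdown perturbs the *mixture* — multiplicative factors on component
weights, an additive shift of the log10 component means, and a multiplier on
event survival — never the gated readouts directly, so the gating and
scoring stages must recover planted effects through the event level.

Replicate structure mirrors an arrayed screen run across several primary
cultures: a shared per-culture random effect on the log component weights
(cultures drift as a whole), plus an independent per-well effect
(transfection/handling noise), both log-normal.

Everything is driven by one seeded ``numpy`` Generator with wells visited in
sorted (plate, well) order, so identical (config, plate map, seed) give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import PlateMap, build_library_layout

LN10 = np.log(10.0)

COMPONENTS = ("negative", "dim", "mid", "bright")


@dataclass(frozen=True)
class MixtureModel:
    """Four-component log10-normal intensity mixture.

    weights sum to 1; component means are strictly increasing from the
    reporter-negative population up to Bright.
    """

    weights: tuple[float, float, float, float]
    mu: tuple[float, float, float, float]
    sigma: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        if w.shape != (4,) or mu.shape != (4,) or sig.shape != (4,):
            raise ValueError("mixture needs exactly 4 components")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
        if (sig <= 0).any():
            raise ValueError("sigma must be > 0")
        if not (np.diff(mu) > 0).all():
            raise ValueError("component means must be strictly increasing")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.asarray(self.weights, float),
            np.asarray(self.mu, float),
            np.asarray(self.sigma, float),
        )


#: Default baseline profile of a cultured reporter population.  The source
#: screen never reports its baseline Bright fraction, so these are package
#: choices: ~10% Bright (stem-enriched), 15% Mid, 20% Dim, 55% negative,
#: with component separations that leave realistic inter-stratum overlap.
DEFAULT_BASELINE = MixtureModel(
    weights=(0.55, 0.20, 0.15, 0.10),
    mu=(1.0, 2.0, 2.6, 3.2),
    sigma=(0.30, 0.25, 0.22, 0.20),
)

#: Quadrant boundaries (log10 intensity) matching DEFAULT_BASELINE.
DEFAULT_BOUNDARIES = (1.5, 2.3, 2.9)


@dataclass(frozen=True)
class EffectSpec:
    """Planted knockdown phenotype for one library target.

    Factors multiply the baseline component weights (then renormalized);
    ``intensity_shift`` moves all component means in log10 units;
    ``viability_factor`` multiplies the per-event survival probability.
    ``ages`` restricts the effect to cultures of those ages, modelling
    age-differential responses; default is both.
    The null effect is all factors 1 and shift 0.
    """

    target_gene: str
    bright_weight_factor: float = 1.0
    mid_weight_factor: float = 1.0
    dim_weight_factor: float = 1.0
    intensity_shift: float = 0.0
    viability_factor: float = 1.0
    ages: tuple[str, ...] = ("pup", "adult")

    def __post_init__(self) -> None:
        for name in ("bright_weight_factor", "mid_weight_factor",
                     "dim_weight_factor", "viability_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def is_null(self) -> bool:
        return (
            self.bright_weight_factor == 1.0
            and self.mid_weight_factor == 1.0
            and self.dim_weight_factor == 1.0
            and self.intensity_shift == 0.0
            and self.viability_factor == 1.0
        )

    def weight_factors(self) -> np.ndarray:
        return np.array(
            [1.0, self.dim_weight_factor, self.mid_weight_factor,
             self.bright_weight_factor]
        )


def compose_effects(specs: Sequence[EffectSpec]) -> EffectSpec:
    """Compose several effect components acting on one well: weight and
    viability factors multiply, intensity shifts add."""
    if not specs:
        return NULL_EFFECT
    if len(specs) == 1:
        return specs[0]
    out = specs[0]
    for s in specs[1:]:
        out = EffectSpec(
            target_gene=out.target_gene or s.target_gene,
            bright_weight_factor=out.bright_weight_factor
            * s.bright_weight_factor,
            mid_weight_factor=out.mid_weight_factor * s.mid_weight_factor,
            dim_weight_factor=out.dim_weight_factor * s.dim_weight_factor,
            intensity_shift=out.intensity_shift + s.intensity_shift,
            viability_factor=out.viability_factor * s.viability_factor,
            ages=tuple(set(out.ages) | set(s.ages)),
        )
    return out


@dataclass
class SimConfig:
    """Generative configuration of one screen run.

    ``effects`` maps a target gene to its planted phenotype — either one
    EffectSpec or a sequence of them (e.g. separate pup- and adult-
    restricted components); the components applicable to a well's culture
    age are composed multiplicatively."""

    baseline: MixtureModel = DEFAULT_BASELINE
    effects: dict[str, EffectSpec | tuple[EffectSpec, ...]] = field(
        default_factory=dict
    )
    n_events_per_well: int = 2000
    base_viability: float = 0.90
    culture_noise_sd: float = 0.10
    well_noise_sd: float = 0.06
    internal_control_gene: str = "Rb1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events_per_well < 1:
            raise ValueError("n_events_per_well must be >= 1")
        if not (0 < self.base_viability <= 1):
            raise ValueError("base_viability must be in (0, 1]")
        if self.culture_noise_sd < 0 or self.well_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


NULL_EFFECT = EffectSpec(target_gene="")


def apply_effect(
    mixture: MixtureModel, effect: EffectSpec
) -> MixtureModel:
    """Noise-free perturbed mixture: weights multiplied and renormalized,
    means shifted."""
    w, mu, sig = mixture.as_arrays()
    w = w * effect.weight_factors()
    w = w / w.sum()
    mu = mu + effect.intensity_shift
    return MixtureModel(tuple(w), tuple(mu), tuple(sig))


def expected_stratum_fractions(
    mixture: MixtureModel, boundaries: Sequence[float]
) -> np.ndarray:
    """Expected viable-event fraction in each gated stratum
    (negative, dim, mid, bright) for fixed log10 boundaries."""
    from scipy.stats import norm

    w, mu, sig = mixture.as_arrays()
    edges = np.concatenate([[-np.inf], np.asarray(boundaries, float), [np.inf]])
    frac = np.zeros(4)
    for c in range(4):
        cdf = norm.cdf(edges, loc=mu[c], scale=sig[c])
        frac += w[c] * np.diff(cdf)
    return frac


def expected_mfi(mixture: MixtureModel) -> float:
    """Expected linear-scale mean fluorescence: sum of component lognormal
    means, E[10^X] = exp(ln10*mu + (ln10*sigma)^2/2)."""
    w, mu, sig = mixture.as_arrays()
    return float(np.sum(w * np.exp(LN10 * mu + 0.5 * (LN10 * sig) ** 2)))


def _effect_for_well(
    config: SimConfig, role: str, target_gene: str, age: str
) -> EffectSpec:
    if role == "target":
        entry = config.effects.get(target_gene)
    elif role == "internal_control":
        entry = config.effects.get(config.internal_control_gene)
    else:
        entry = None
    if entry is None:
        return NULL_EFFECT
    specs = (entry,) if isinstance(entry, EffectSpec) else tuple(entry)
    applicable = [s for s in specs if age in s.ages]
    return compose_effects(applicable)


def simulate_screen(
    config: SimConfig, plate_map: PlateMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole screen.

    Returns (events, truth): events has one row per cell event
    (well_key, intensity, viable); truth records per well the realized
    component weights, the applied effect, and the survival probability.
    """
    rng = np.random.default_rng(config.seed)
    w0, mu0, sig0 = config.baseline.as_arrays()

    wells = plate_map.wells  # already sorted by well_key
    cultures = sorted(wells["culture_id"].unique())
    culture_eps = {
        c: rng.normal(0.0, config.culture_noise_sd, size=4)
        if config.culture_noise_sd > 0
        else np.zeros(4)
        for c in cultures
    }

    n = config.n_events_per_well
    event_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []

    for rec in wells.itertuples():
        eff = _effect_for_well(config, rec.role, rec.target_gene,
                               rec.culture_age)
        well_eps = (
            rng.normal(0.0, config.well_noise_sd, size=4)
            if config.well_noise_sd > 0
            else np.zeros(4)
        )
        w = w0 * eff.weight_factors() * np.exp(
            culture_eps[rec.culture_id] + well_eps
        )
        w = w / w.sum()
        mu = mu0 + eff.intensity_shift
        p_viable = min(1.0, config.base_viability * eff.viability_factor)

        counts = rng.multinomial(n, w)
        log_int = np.concatenate(
            [
                rng.normal(mu[c], sig0[c], size=counts[c])
                for c in range(4)
            ]
        )
        viable = (rng.random(n) < p_viable).astype(np.int8)
        event_frames.append(
            pd.DataFrame(
                {
                    "well_key": rec.well_key,
                    "intensity": np.power(10.0, log_int),
                    "viable": viable,
                }
            )
        )
        truth_rows.append(
            dict(
                well_key=rec.well_key,
                target_gene=rec.target_gene,
                role=rec.role,
                effect_gene=eff.target_gene,
                w_negative=w[0],
                w_dim=w[1],
                w_mid=w[2],
                w_bright=w[3],
                p_viable=p_viable,
            )
        )

    events = pd.concat(event_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return events, truth


def null_screen_fixture(
    n_targets: int = 1440,
    n_replicates: int = 3,
    seed: int = 0,
    n_events_per_well: int = 2000,
    well_noise_sd: float = 0.03,
    ages: Sequence[str] | None = None,
    n_nontargeted_controls: int = 12,
) -> tuple[SimConfig, PlateMap]:
    """All-null screen for calibrating the Z pipeline.

    The harness's contract is that the downstream average-Z distribution
    over targets approximates Normal(0, 1/n_replicates), so its design
    suppresses the departures the production layout would induce:
    replicates are independent (no shared culture effect), plates are
    control-rich (12 nontargeted wells each, so plate normalization adds
    negligible plate-shared noise), and the per-well weight noise is kept
    small enough that near-symmetric event-sampling noise dominates the
    readout (log-normal weight noise skews the normalized ratio right and
    would bias the upper tail).
    """
    if n_targets < 50:
        raise ValueError("n_targets must be >= 50 for a meaningful null")
    if ages is None:
        ages = ["pup" if i % 2 == 0 else "adult" for i in range(n_replicates)]
    cultures = [(f"rep{i + 1}", ages[i]) for i in range(n_replicates)]
    plate_map, _ = build_library_layout(
        n_targets=n_targets, cultures=cultures,
        n_nontargeted_controls=n_nontargeted_controls,
    )
    config = SimConfig(
        effects={},
        n_events_per_well=n_events_per_well,
        culture_noise_sd=0.0,
        well_noise_sd=well_noise_sd,
        seed=seed,
    )
    return config, plate_map


# ---------------------------------------------------------------------------
# packaged calibration fixtures


def load_effect_yaml(path: str | Path) -> EffectSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "ages" in doc:
        doc["ages"] = tuple(doc["ages"])
    return EffectSpec(**doc)


def save_effect_yaml(effect: EffectSpec, path: str | Path) -> None:
    doc = dict(
        target_gene=effect.target_gene,
        bright_weight_factor=float(effect.bright_weight_factor),
        mid_weight_factor=float(effect.mid_weight_factor),
        dim_weight_factor=float(effect.dim_weight_factor),
        intensity_shift=float(effect.intensity_shift),
        viability_factor=float(effect.viability_factor),
        ages=list(effect.ages),
    )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def rb1_effect() -> EffectSpec:
    """The committed Rb1 positive-control phenotype (calibrated once so the
    emergent gated readout changes match the validation experiment:
    ~32% %Bright reduction, ~40% MFI reduction)."""
    from importlib.resources import files

    path = files("flowscreen").joinpath("data/rb1_effect.yaml")
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if "ages" in doc:
        doc["ages"] = tuple(doc["ages"])
    return EffectSpec(**doc)


def default_screen_effects(
    library_genes: Sequence[str],
    seed: int = 0,
    tau_shared: float = 0.02,
    tau_pup: float = 0.0,
    tau_adult: float = 0.072,
    mfi_shift_sd: float = 0.012,
    shift_coupling: float = 0.25,
) -> dict[str, tuple[EffectSpec, EffectSpec]]:
    """Default planted-effect landscape for a full simulated screen:
    a variance-component model of knockdown responses.

    Every library target g carries a latent log effect on the Bright
    compartment weight with a component shared across culture ages and an
    age-specific component:

        log f_bright(g, age) = b_shared(g) + b_age(g),
        b_shared ~ N(0, tau_shared^2),  b_age ~ N(0, tau_age^2),

    realized once per screen, so the response is *consistent across the
    replicate cultures of an age* — this is what makes per-replicate
    Z-scores correlate within an age group and is the structure the
    pup-versus-adult ΔZ comparison is designed to detect.  The intensity
    shift couples the overall fluorescence to the Bright-weight effect
    (``shift_coupling`` log10 units per log10 of the weight factor) plus
    an independent shared latent shift (sd ``mfi_shift_sd`` log10 units)
    so the two screen parameters are correlated but not redundant.

    The defaults emulate a screen in which most knockdowns barely move
    the readout, pup responses are noise-dominated, and adult cultures
    respond more consistently (larger age-specific variance).

    Returns {gene: (pup component, adult component)}.
    """
    rng = np.random.default_rng(seed)
    genes = list(library_genes)
    n = len(genes)
    b_shared = rng.normal(0.0, tau_shared, n) if tau_shared > 0 else np.zeros(n)
    b_pup = rng.normal(0.0, tau_pup, n) if tau_pup > 0 else np.zeros(n)
    b_adult = rng.normal(0.0, tau_adult, n) if tau_adult > 0 else np.zeros(n)
    m = rng.normal(0.0, mfi_shift_sd, n) if mfi_shift_sd > 0 else np.zeros(n)

    effects: dict[str, tuple[EffectSpec, EffectSpec]] = {}
    for i, gene in enumerate(genes):
        per_age = []
        for age, b_age in (("pup", b_pup[i]), ("adult", b_adult[i])):
            f = float(np.exp(b_shared[i] + b_age))
            shift = shift_coupling * np.log10(f) + m[i]
            per_age.append(
                EffectSpec(
                    target_gene=gene,
                    bright_weight_factor=f,
                    intensity_shift=float(shift),
                    ages=(age,),
                )
            )
        effects[gene] = tuple(per_age)
    return effects
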