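"""Seeded generator of synthetic feed datasets.

The generator emulates the statistical structure the evaluation relies
on: proximate compositions spread over the composition ranges of the
packaged reference dataset, apparent digestibility coefficients that
decline linearly with crude fiber (so observed DE is strongly and
negatively correlated with CF, and the digestible nutrient fractions are
too), and — for exercising the bias statistics — predictions with
injectable mean and linear bias.

It is a test harness, not a digestion model: digestibility is a linear
function of fiber with Gaussian noise, clamped to [0, 1], and nothing
else (no associative effects, no processing or particle-size effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset, DigestibleFractions, FeedRecord, ProximateComposition
from .energy import DEFAULT_GE, GrossEnergyCoefficients, observed_de_from_digestible

__all__ = ["SyntheticConfig", "generate_feeds", "generate_biased_predictions"]

# Baseline apparent digestibility coefficients at the low-fiber end,
# and their linear decline per % DM of crude fiber above cf_min.
_DEFAULT_BASES = {"cp": 0.80, "cf": 0.30, "nfe": 0.85, "ee": 0.60}
_DEFAULT_SLOPES = {"cp": 0.008, "cf": -0.004, "nfe": 0.010, "ee": 0.015}


@dataclass(frozen=True)
class SyntheticConfig:
    """Distributional parameters and seed for the feed generator.

    Composition ranges default to those of the packaged reference
    dataset (% DM). ``digestibility_slopes`` give the per-% DM decline of
    each nutrient's digestibility coefficient with crude fiber (a
    negative slope means digestibility rises with fiber, as crude-fiber
    digestibility itself tends to); ``digestibility_bases`` are the
    coefficients at the low-fiber end. ``bias_*`` control
    :func:`generate_biased_predictions` only.
    """

    n: int = 32
    seed: int = 0
    cp_range: tuple[float, float] = (6.3, 21.6)
    cf_range: tuple[float, float] = (3.5, 31.9)
    ee_range: tuple[float, float] = (2.0, 5.3)
    om_range: tuple[float, float] = (88.0, 96.0)
    digestibility_bases: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASES)
    )
    digestibility_slopes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SLOPES)
    )
    digestibility_noise_sd: float = 0.03
    bias_intercept: float = 0.0
    bias_slope: float = 0.0
    bias_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        for name in ("cp_range", "cf_range", "ee_range", "om_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.digestibility_noise_sd < 0 or self.bias_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for key in ("cp", "cf", "nfe", "ee"):
            if key not in self.digestibility_bases or key not in self.digestibility_slopes:
                raise ValueError(f"digestibility bases/slopes must cover {key!r}")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # one independent stream per generate call, derived from the config seed
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def generate_feeds(
    cfg: SyntheticConfig, g: GrossEnergyCoefficients = DEFAULT_GE
) -> Dataset:
    """Generate a fully reproducible synthetic feed dataset.

    CP, CF and EE are sampled uniformly over their ranges; NFE is set so
    the organic-matter total lands uniformly inside ``om_range``.
    Digestibility coefficients are ``base - slope * (cf - cf_min)`` plus
    Gaussian noise, clamped to [0, 1]; digestible fractions are
    coefficient x crude fraction, and observed DE is their summative
    energy value under the default heats of combustion.
    """
    rng = _rng(cfg, stream=0)
    n = cfg.n
    cp = rng.uniform(*cfg.cp_range, n)
    cf = rng.uniform(*cfg.cf_range, n)
    ee = rng.uniform(*cfg.ee_range, n)
    om = rng.uniform(*cfg.om_range, n)
    nfe = np.clip(om - cp - cf - ee, 0.0, None)

    cf_min = cfg.cf_range[0]
    crude = {"cp": cp, "cf": cf, "nfe": nfe, "ee": ee}
    coeffs = {}
    for key in ("cp", "cf", "nfe", "ee"):
        base = cfg.digestibility_bases[key]
        slope = cfg.digestibility_slopes[key]
        noise = rng.normal(0.0, cfg.digestibility_noise_sd, n)
        coeffs[key] = np.clip(base - slope * (cf - cf_min) + noise, 0.0, 1.0)

    records = []
    for i in range(n):
        comp = ProximateComposition(
            cp=float(cp[i]), cf=float(cf[i]), nfe=float(nfe[i]), ee=float(ee[i])
        )
        dig = DigestibleFractions(
            dcp=float(coeffs["cp"][i] * cp[i]),
            dcf=float(coeffs["cf"][i] * cf[i]),
            dnfe=float(coeffs["nfe"][i] * nfe[i]),
            dee=float(coeffs["ee"][i] * ee[i]),
        )
        records.append(
            FeedRecord(
                id=i + 1,
                source="synthetic",
                kind="mixed diet",
                composition=comp,
                digestible=dig,
                de_observed=observed_de_from_digestible(dig, g),
            )
        )
    return Dataset(tuple(records), name=f"synthetic(seed={cfg.seed}, n={n})")


def generate_biased_predictions(ds: Dataset, cfg: SyntheticConfig) -> np.ndarray:
    """Predictions with injected mean and linear bias.

    p_i = o_i - bias_intercept - bias_slope * (o_i - mean(o)) + noise,
    so the residual o - p has mean ``bias_intercept`` and grows linearly
    with observed DE at rate ``bias_slope``. Used for parameter-recovery
    tests of the bias regression and the MSEP decomposition.
    """
    rng = _rng(cfg, stream=1)
    o = np.array([r.de_observed for r in ds])
    noise = rng.normal(0.0, cfg.bias_noise_sd, o.size) if cfg.bias_noise_sd > 0 else 0.0
    return o - cfg.bias_intercept - cfg.bias_slope * (o - o.mean()) + noise
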