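"""Synthetic per-crypt immunofluorescence intensity cohorts.

Real cohorts of this kind come from quantitative immunofluorescence on
colonic sections: each crypt contributes one mean intensity per marker —
NDUFB8 (complex I subunit), MTCO1 (complex IV subunit) and the
mitochondrial mass markers TOMM20 and VDAC1.  PolgA mutator mice carry a
mosaic of crypts in which one or both respiratory-chain complexes have
dropped out, while mitochondrial mass is unchanged.  This module
generates tables with exactly that statistical structure so the z-score
classifier can be tested with known ground truth.

Generative model (per crypt):

* a deficiency category is drawn from the genotype's category mixture;
* the mass markers TOMM20 and VDAC1 are lognormal around the control
  means regardless of category (deficiency does not change mass);
* each OXPHOS marker is the crypt's own TOMM20 draw times a lognormal
  mass-normalized level whose mean is reduced by ``deficiency_effect``
  when the corresponding complex is deficient.

Tying the OXPHOS markers to the crypt's TOMM20 draw mirrors the biology
(more mitochondria means more of every mitochondrial protein) and means
``control_cv`` is exactly the coefficient of variation of the
mass-normalized level the classifier scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("NORMAL", "CI_DEF", "CIV_DEF", "CI_CIV_DEF")
GENOTYPES = ("+/+", "+/mut", "mut/mut")

OXPHOS_MARKERS = ("ndufb8", "mtco1")
MASS_MARKERS = ("tomm20", "vdac1")
ALL_MARKERS = OXPHOS_MARKERS + MASS_MARKERS

#: which markers are reduced in each deficiency category
_AFFECTED = {
    "NORMAL": (),
    "CI_DEF": ("ndufb8",),
    "CIV_DEF": ("mtco1",),
    "CI_CIV_DEF": ("ndufb8", "mtco1"),
}

#: mixture weights over (NORMAL, CI_DEF, CIV_DEF, CI_CIV_DEF) per genotype;
#: heterozygote and homozygote weights follow the reported mosaic prevalences
DEFAULT_CATEGORY_PROBS: dict[str, tuple[float, float, float, float]] = {
    "+/+": (1.0, 0.0, 0.0, 0.0),
    "+/mut": (0.5282, 0.3188, 0.0424, 0.1106),
    "mut/mut": (0.0, 0.531, 0.0, 0.469),
}

DEFAULT_CONTROL_MEANS = {
    "ndufb8": 1200.0,
    "mtco1": 1500.0,
    "tomm20": 1800.0,
    "vdac1": 1600.0,
}

INTENSITY_COLUMNS = [
    "mouse_id",
    "genotype",
    "crypt_id",
    "ndufb8",
    "mtco1",
    "tomm20",
    "vdac1",
    "true_category",
]

_GENOTYPE_PREFIX = {"+/+": "wt", "+/mut": "het", "mut/mut": "hom"}


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and CV."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


@dataclass
class IntensityConfig:
    """Configuration of the synthetic intensity cohort.

    Parameters
    ----------
    n_mice_per_genotype : int
        Mice per genotype arm (4 in the emulated study design).
    crypts_per_mouse : int
        Crypts scored per mouse (~200 per mouse in the emulated design).
    control_means : mapping
        Mean intensity of each marker in OXPHOS-normal tissue, arbitrary
        fluorescence units.
    control_cv : float or mapping
        Coefficient of variation per marker.  For ``ndufb8``/``mtco1``
        this is the CV of the mass-normalized level; for the mass
        markers it is the CV of the raw intensity.  A scalar is
        broadcast to all markers.
    category_probs : mapping
        Per genotype, mixture weights over ``CATEGORIES``.
    deficiency_effect : float
        Fractional reduction of the affected marker's mass-normalized
        mean, in (0, 1].  The default 0.6 puts deficient crypts far
        below the z = −4.5 calling line.
    mouse_effect_sd : float
        SD of an optional lognormal mouse-level multiplier on the
        mass-normalized OXPHOS levels (0 = mice exchangeable).
    seed : int
        Seed of the generator; output is a pure function of the config.
    """

    n_mice_per_genotype: int = 4
    crypts_per_mouse: int = 200
    control_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEANS)
    )
    control_cv: float | Mapping[str, float] = 0.10
    category_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {g: p for g, p in DEFAULT_CATEGORY_PROBS.items()}
    )
    deficiency_effect: float = 0.6
    mouse_effect_sd: float = 0.0
    seed: int = 0

    def cv_for(self, marker: str) -> float:
        if isinstance(self.control_cv, Mapping):
            return float(self.control_cv[marker])
        return float(self.control_cv)

    def validate(self) -> None:
        if self.n_mice_per_genotype < 1:
            raise ValueError("n_mice_per_genotype must be a positive integer")
        if self.crypts_per_mouse < 1:
            raise ValueError("crypts_per_mouse must be a positive integer")
        for m in ALL_MARKERS:
            if m not in self.control_means:
                raise ValueError(f"control_means is missing marker {m!r}")
            if not self.control_means[m] > 0:
                raise ValueError(f"control_means[{m!r}] must be positive")
            cv = self.cv_for(m)
            if not 0.0 < cv < 1.0:
                raise ValueError(f"control_cv for {m!r} must lie in (0, 1)")
        if not 0.0 < self.deficiency_effect <= 1.0:
            raise ValueError("deficiency_effect must lie in (0, 1]")
        if self.mouse_effect_sd < 0:
            raise ValueError("mouse_effect_sd must be nonnegative")
        for geno, probs in self.category_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (len(CATEGORIES),):
                raise ValueError(
                    f"category_probs[{geno!r}] must have {len(CATEGORIES)} entries"
                )
            if np.any(p < 0):
                raise ValueError(f"category_probs[{geno!r}] has negative entries")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"category_probs[{geno!r}] must sum to 1 (±1e-12)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["control_means"] = dict(self.control_means)
        if isinstance(self.control_cv, Mapping):
            d["control_cv"] = dict(self.control_cv)
        d["category_probs"] = {g: list(map(float, p)) for g, p in self.category_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "IntensityConfig":
        return cls(**dict(d))


def generate_intensity_cohort(config: IntensityConfig) -> pd.DataFrame:
    """Generate the per-crypt intensity table for all genotypes in the config.

    Returns a DataFrame with columns ``mouse_id, genotype, crypt_id,
    ndufb8, mtco1, tomm20, vdac1, true_category``.  ``true_category`` is
    ground truth for recovery tests only; the classifier never reads it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    effect = config.deficiency_effect
    mean_t = config.control_means["tomm20"]

    rows: list[pd.DataFrame] = []
    for geno in config.category_probs:
        probs = np.asarray(config.category_probs[geno], dtype=float)
        prefix = _GENOTYPE_PREFIX.get(geno, geno.replace("/", ""))
        for i in range(config.n_mice_per_genotype):
            n = config.crypts_per_mouse
            cat_idx = rng.choice(len(CATEGORIES), size=n, p=probs)
            cats = np.asarray(CATEGORIES)[cat_idx]
            mouse_mult = (
                rng.lognormal(0.0, config.mouse_effect_sd)
                if config.mouse_effect_sd > 0
                else 1.0
            )

            cols: dict[str, np.ndarray] = {}
            for m in MASS_MARKERS:
                mu, sg = _lognormal_params(config.control_means[m], config.cv_for(m))
                cols[m] = rng.lognormal(mu, sg, size=n)
            for m in OXPHOS_MARKERS:
                ratio_mean = config.control_means[m] / mean_t
                mu, sg = _lognormal_params(ratio_mean, config.cv_for(m))
                ratio = rng.lognormal(mu, sg, size=n) * mouse_mult
                affected = np.isin(cats, [c for c in CATEGORIES if m in _AFFECTED[c]])
                ratio = np.where(affected, ratio * (1.0 - effect), ratio)
                cols[m] = cols["tomm20"] * ratio

            rows.append(
                pd.DataFrame(
                    {
                        "mouse_id": f"{prefix}{i + 1}",
                        "genotype": geno,
                        "crypt_id": [f"c{j + 1:05d}" for j in range(n)],
                        "ndufb8": cols["ndufb8"],
                        "mtco1": cols["mtco1"],
                        "tomm20": cols["tomm20"],
                        "vdac1": cols["vdac1"],
                        "true_category": cats,
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    return out[INTENSITY_COLUMNS]


def write_intensities(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_intensities(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in INTENSITY_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table is missing columns: {missing}")
    return df
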