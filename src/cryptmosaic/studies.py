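"""Reusable study drivers: prevalence recovery and effect-size recovery.

These wrap the generator → classifier → GLMM stack into the two
simulation studies the package uses to validate itself:

* :func:`prevalence_recovery` — generate a mosaic cohort with known
  category prevalences, classify it against a separately generated
  wild-type reference cohort, and compare called to true percentages;
* :func:`effect_recovery_study` — repeatedly simulate two-arm labelling
  cohorts with a known division-rate ratio and collect the Poisson
  random-intercept GLMM's rate-ratio estimates and CI coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cryptmosaic.glmm import GLMMSpec, fit_glmm, make_design, wald_summary
from cryptmosaic.labelling import CohortConfig, CryptSimParams, simulate_label_cohort
from cryptmosaic.oxphos_classifier import build_reference, classify_cohort
from cryptmosaic.synthetic_cohort import (
    CATEGORIES,
    IntensityConfig,
    generate_intensity_cohort,
)

#: reported mosaic prevalences over (NORMAL, CI_DEF, CIV_DEF, CI_CIV_DEF)
HETEROZYGOTE_PROBS = (0.5282, 0.3188, 0.0424, 0.1106)
HOMOZYGOTE_PROBS = (0.0, 0.531, 0.0, 0.469)


@dataclass
class PrevalenceRecovery:
    """Called vs generating category percentages for one synthetic cohort."""

    genotype: str
    n_crypts: int
    true_pct: dict[str, float]
    called_pct: dict[str, float]
    binomial_se_pct: dict[str, float]

    def within_3se(self) -> bool:
        """Called percentages within 3 binomial SEs of the generating truth.

        Restricted to the mixture's categories (true prevalence > 0),
        whose binomial SE is nonzero.
        """
        return all(
            abs(self.called_pct[c] - self.true_pct[c]) <= 3.0 * self.binomial_se_pct[c]
            for c in CATEGORIES
            if self.true_pct[c] > 0
        )


def prevalence_recovery(
    category_probs: Sequence[float],
    genotype: str = "+/mut",
    n_crypts: int = 10_000,
    n_mice: int = 4,
    n_control_mice: int = 4,
    control_crypts_per_mouse: int = 200,
    deficiency_effect: float = 0.6,
    control_cv: float = 0.10,
    threshold: float = -4.5,
    seed: int = 0,
) -> PrevalenceRecovery:
    """Classify a synthetic mosaic cohort against a synthetic wild-type reference.

    The mosaic cohort's ``n_crypts`` are spread over ``n_mice`` mice;
    the reference cohort is generated independently (different seed
    stream) from pure-NORMAL wild-type mice.
    """
    rng = np.random.default_rng(seed)
    seed_control, seed_mosaic = (int(s) for s in rng.integers(2**31, size=2))

    control_cfg = IntensityConfig(
        n_mice_per_genotype=n_control_mice,
        crypts_per_mouse=control_crypts_per_mouse,
        control_cv=control_cv,
        deficiency_effect=deficiency_effect,
        category_probs={"+/+": (1.0, 0.0, 0.0, 0.0)},
        seed=seed_control,
    )
    controls = generate_intensity_cohort(control_cfg)

    per_mouse, rem = divmod(n_crypts, n_mice)
    if rem:
        raise ValueError("n_crypts must be divisible by n_mice")
    mosaic_cfg = replace(
        control_cfg,
        n_mice_per_genotype=n_mice,
        crypts_per_mouse=per_mouse,
        category_probs={genotype: tuple(category_probs)},
        seed=seed_mosaic,
    )
    mosaic = generate_intensity_cohort(mosaic_cfg)

    reference = build_reference(controls)
    calls = classify_cohort(mosaic, reference=reference, threshold=threshold)
    counts = calls["category"].value_counts()
    called_pct = {c: 100.0 * counts.get(c, 0) / n_crypts for c in CATEGORIES}
    true_pct = {c: 100.0 * p for c, p in zip(CATEGORIES, category_probs)}
    se_pct = {
        c: 100.0 * np.sqrt(p * (1.0 - p) / n_crypts)
        for c, p in zip(CATEGORIES, category_probs)
    }
    return PrevalenceRecovery(
        genotype=genotype,
        n_crypts=n_crypts,
        true_pct=true_pct,
        called_pct=called_pct,
        binomial_se_pct=se_pct,
    )


@dataclass
class EffectRecovery:
    """Replicate-level GLMM estimates of a known division-rate ratio."""

    true_rate_ratio: float
    estimates: pd.DataFrame  # per replicate: log_rr, se, covered, converged
    n_replicates: int

    @property
    def mean_pct_increase(self) -> float:
        return float(100.0 * (np.exp(self.estimates["log_rr"]).mean() - 1.0))

    @property
    def mc_se_pct(self) -> float:
        """Monte-Carlo SE of the mean percentage increase."""
        rr = np.exp(self.estimates["log_rr"])
        return float(100.0 * rr.std(ddof=1) / np.sqrt(len(rr)))

    @property
    def coverage(self) -> float:
        return float(self.estimates["covered"].mean())


def effect_recovery_study(
    n_replicates: int = 200,
    rate_ratio: float = 1.2,
    n_mice_per_group: int = 20,
    crypts_per_mouse: int = 50,
    mouse_frailty_sd: float = 0.2,
    response: str = "lgr5_dual",
    exposure: str = "lgr5_total",
    base_params: CryptSimParams | None = None,
    seed: int = 0,
) -> EffectRecovery:
    """Repeatedly simulate two-arm cohorts and fit the Poisson GLMM.

    Each replicate simulates an OXPHOS-normal arm and a deficient arm
    whose division rate is ``rate_ratio`` times higher, with disjoint
    mice and a lognormal mouse frailty, then fits a Poisson
    random-intercept GLMM with a log-exposure offset and records the
    rate-ratio estimate and whether its 95% Wald CI covers the truth.
    """
    base = base_params if base_params is not None else CryptSimParams()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(2**31, size=n_replicates)
    rows = []
    for rep_seed in rep_seeds:
        cfg = CohortConfig(
            group_params={
                "NORMAL": replace(base, rate_multiplier=1.0, group_label="NORMAL"),
                "DEF": replace(base, rate_multiplier=rate_ratio, group_label="DEF"),
            },
            crypts_per_group={
                "NORMAL": n_mice_per_group * crypts_per_mouse,
                "DEF": n_mice_per_group * crypts_per_mouse,
            },
            n_mice=n_mice_per_group,
            mouse_frailty_sd=mouse_frailty_sd,
            shared_mice=False,
            seed=int(rep_seed),
        )
        counts = simulate_label_cohort(cfg)
        designed, terms = make_design(counts, "group_label", reference="NORMAL")
        spec = GLMMSpec(
            family="poisson",
            response=response,
            fixed_effects=terms,
            exposure=exposure,
            group="mouse_id",
        )
        fit = fit_glmm(designed, spec)
        w = wald_summary(fit, terms[0])
        rows.append(
            {
                "log_rr": w.estimate,
                "se": w.se,
                "covered": bool(w.ci_low <= rate_ratio <= w.ci_high),
                "converged": fit.converged,
                "sigma_u": fit.sigma_u,
            }
        )
    return EffectRecovery(
        true_rate_ratio=rate_ratio,
        estimates=pd.DataFrame(rows),
        n_replicates=n_replicates,
    )
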