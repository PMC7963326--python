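"""End-to-end orchestration: simulate → classify → join → fit → report.

The pipeline emulates the intra-mouse mosaic analysis: intensities are
generated for a mosaic genotype plus wild-type controls, every crypt is
z-score classified against the pooled wild-type reference, label counts
are simulated for the same crypts (their true category driving the
division rate, standing in for the serial-section match), the called
category is joined onto the counts by (mouse_id, crypt_id), and the
configured count GLMMs are fitted contrasting each deficient category
against OXPHOS-normal crypts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cryptmosaic._version import __version__ as _pkg_version
from cryptmosaic.glmm import GLMMFit, GLMMSpec, fit_glmm, make_design
from cryptmosaic.labelling import (
    COUNT_COLUMNS,
    CryptSimParams,
    build_schedule,
    simulate_counts_for_crypts,
)
from cryptmosaic.oxphos_classifier import (
    DEFAULT_THRESHOLD,
    build_reference,
    classify_cohort,
    mass_marker_qc,
    summarize_categories,
)
from cryptmosaic.synthetic_cohort import (
    CATEGORIES,
    IntensityConfig,
    generate_intensity_cohort,
)

logger = logging.getLogger("cryptmosaic.pipeline")

#: division-rate multipliers emulating the reported proliferation pattern
DEFAULT_CATEGORY_MULTIPLIERS = {
    "NORMAL": 1.0,
    "CI_DEF": 1.2,
    "CIV_DEF": 0.8,
    "CI_CIV_DEF": 1.2,
}

DEFAULT_MODELS: tuple[dict, ...] = (
    {"response": "lgr5_cldu", "family": "poisson", "exposure": "lgr5_total"},
    {"response": "lgr5_idu", "family": "poisson", "exposure": "lgr5_total"},
    {"response": "lgr5_dual", "family": "poisson", "exposure": "lgr5_total"},
    {"response": "cldu", "family": "poisson", "exposure": "total_cells"},
    {"response": "idu", "family": "poisson", "exposure": "total_cells"},
    {"response": "dual", "family": "poisson", "exposure": "total_cells"},
    {"response": "ki67", "family": "poisson", "exposure": "total_cells"},
    {"response": "total_cells", "family": "negbin", "exposure": None},
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; the seed drives every stochastic stage."""

    intensity: IntensityConfig = field(default_factory=IntensityConfig)
    threshold: float = DEFAULT_THRESHOLD
    mass_marker: str = "tomm20"
    control_genotype: str = "+/+"
    mosaic_genotype: str = "+/mut"
    category_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MULTIPLIERS)
    )
    label_params: CryptSimParams = field(default_factory=CryptSimParams)
    mouse_frailty_sd: float = 0.2
    models: Sequence[Mapping] = field(default_factory=lambda: [dict(m) for m in DEFAULT_MODELS])
    quadrature_points: int = 20
    seed: int = 0

    def validate(self) -> None:
        self.intensity.validate()
        self.label_params.validate()
        for cat in CATEGORIES:
            if cat not in self.category_multipliers:
                raise ValueError(f"category_multipliers is missing {cat!r}")
        for m in self.models:
            if "response" not in m:
                raise ValueError("every model needs a 'response'")
            if m["response"] not in COUNT_COLUMNS[3:]:
                raise ValueError(
                    f"unknown response column {m['response']!r}; "
                    f"counts tables have {COUNT_COLUMNS[3:]}"
                )
            expo = m.get("exposure")
            if expo is not None and expo not in COUNT_COLUMNS[3:]:
                raise ValueError(f"unknown exposure column {expo!r}")
            if m.get("family", "poisson") not in ("poisson", "negbin"):
                raise ValueError(f"unknown family {m.get('family')!r}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {
            "intensity": self.intensity.to_dict(),
            "threshold": self.threshold,
            "mass_marker": self.mass_marker,
            "control_genotype": self.control_genotype,
            "mosaic_genotype": self.mosaic_genotype,
            "category_multipliers": dict(self.category_multipliers),
            "label_params": asdict(self.label_params),
            "mouse_frailty_sd": self.mouse_frailty_sd,
            "models": [dict(m) for m in self.models],
            "quadrature_points": self.quadrature_points,
            "seed": self.seed,
        }
        return d


def run_intra_mouse_analysis(
    calls: pd.DataFrame,
    counts: pd.DataFrame,
    models: Sequence[Mapping] = DEFAULT_MODELS,
    quadrature_points: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GLMMFit]]:
    """Join called categories onto counts and fit the configured GLMMs.

    Crypts in the OXPHOS-normal category are the reference; each
    deficient category is contrasted against it.  Returns (joined table,
    tidy results table, fits).  If every crypt is NORMAL there is
    nothing to contrast and fitting is skipped with an explanatory log
    message (empty results).
    """
    key = ["mouse_id", "crypt_id"]
    joined = counts.merge(calls[key + ["category"]], on=key, how="inner")
    if joined.empty:
        raise ValueError("join produced zero matches on (mouse_id, crypt_id)")
    n_lost = len(counts) - len(joined)
    if n_lost:
        logger.info("join dropped %d count records without a matching call", n_lost)
    logger.info("joined %d crypts across %d mice", len(joined), joined["mouse_id"].nunique())

    present = [c for c in pd.unique(joined["category"]) if c != "NORMAL"]
    if not present:
        logger.info("all crypts are OXPHOS-normal; no contrast to fit, skipping models")
        return joined, pd.DataFrame(), []

    designed, term_cols = make_design(joined, "category", reference="NORMAL")
    fits: list[GLMMFit] = []
    frames = []
    for m in models:
        spec = GLMMSpec(
            family=m.get("family", "poisson"),
            response=m["response"],
            fixed_effects=term_cols,
            exposure=m.get("exposure"),
            group="mouse_id",
            quadrature_points=quadrature_points,
        )
        fit = fit_glmm(designed, spec)
        fits.append(fit)
        frames.append(fit.summary_frame())
        logger.info(
            "fitted %s GLMM for %s: loglik=%.2f sigma_u=%.3f converged=%s",
            spec.family,
            spec.response,
            fit.loglik,
            fit.sigma_u,
            fit.converged,
        )
    results = pd.concat(frames, ignore_index=True)
    return joined, results, fits


def _plot_tables(calls: pd.DataFrame, summary: pd.DataFrame, joined: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Long-format tables mirroring the dot-plot and bar-chart panels."""
    z_long = calls.melt(
        id_vars=["mouse_id", "genotype", "crypt_id", "category"],
        value_vars=["z_ci", "z_civ", "z_mass"],
        var_name="score",
        value_name="z",
    )
    frac = joined.copy()
    for num, den, name in [
        ("cldu", "total_cells", "frac_cldu"),
        ("idu", "total_cells", "frac_idu"),
        ("dual", "total_cells", "frac_dual"),
        ("ki67", "total_cells", "frac_ki67"),
        ("lgr5_cldu", "lgr5_total", "lgr5_frac_cldu"),
        ("lgr5_idu", "lgr5_total", "lgr5_frac_idu"),
        ("lgr5_dual", "lgr5_total", "lgr5_frac_dual"),
    ]:
        frac[name] = frac[num] / frac[den]
    frac_long = frac.melt(
        id_vars=["mouse_id", "category", "crypt_id"],
        value_vars=[c for c in frac.columns if c.startswith(("frac_", "lgr5_frac_"))],
        var_name="measure",
        value_name="fraction",
    )
    return {"plot_zscores": z_long, "plot_category_pct": summary, "plot_label_fractions": frac_long}


def run_full(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the whole pipeline and write all artifacts under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``).  Outputs
    are a pure function of the config, including its seed.
    """
    config.validate()  # fail fast, before any simulation
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seed_counts = int(rng.integers(2**31))

    logger.info("stage 1/5: simulating intensity cohort (seed=%d)", config.intensity.seed)
    intensity_cfg = replace(config.intensity, seed=config.seed)
    intensities = generate_intensity_cohort(intensity_cfg)
    logger.info("generated %d crypt intensity records", len(intensities))

    logger.info("stage 2/5: classifying crypts against %s reference", config.control_genotype)
    controls = intensities[intensities["genotype"] == config.control_genotype]
    reference = build_reference(controls, mass_marker=config.mass_marker)
    calls = classify_cohort(
        intensities,
        reference=reference,
        threshold=config.threshold,
    )
    summary = summarize_categories(calls)
    qc = mass_marker_qc(intensities, reference, threshold=config.threshold)
    logger.info(
        "classified %d crypts (%d mass-QC flags)", len(calls), qc.n_flagged
    )

    logger.info("stage 3/5: simulating label counts for %s crypts", config.mosaic_genotype)
    mosaic = intensities[intensities["genotype"] == config.mosaic_genotype]
    if mosaic.empty:
        raise ValueError(f"no crypts with mosaic genotype {config.mosaic_genotype!r}")
    crypt_table = mosaic[["mouse_id", "crypt_id", "true_category"]].rename(
        columns={"true_category": "category"}
    )
    params_by_category = {
        cat: replace(config.label_params, rate_multiplier=mult, group_label=cat)
        for cat, mult in config.category_multipliers.items()
    }
    counts = simulate_counts_for_crypts(
        crypt_table,
        params_by_category,
        schedule=build_schedule(),
        mouse_frailty_sd=config.mouse_frailty_sd,
        seed=seed_counts,
    )
    logger.info("simulated counts for %d crypts", len(counts))

    logger.info("stage 4/5: intra-mouse GLMM contrasts vs OXPHOS-normal crypts")
    mosaic_calls = calls[calls["genotype"] == config.mosaic_genotype]
    joined, results, fits = run_intra_mouse_analysis(
        mosaic_calls, counts, config.models, config.quadrature_points
    )

    logger.info("stage 5/5: writing artifacts to %s", out)
    artifacts = {
        "intensities": intensities,
        "calls": calls,
        "category_summary": summary,
        "mass_qc_counts": qc.per_genotype_counts,
        "counts": counts,
        "joined": joined,
        "glmm_results": results,
    }
    artifacts.update(_plot_tables(calls, summary, joined))
    paths = {}
    for name, df in artifacts.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
        "record_counts": {name: len(df) for name, df in artifacts.items()},
        "artifacts": paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d artifacts", len(paths) + 1)
    return manifest


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "cryptmosaic": _pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
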