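"""Per-crypt OXPHOS deficiency calling by wild-type-referenced z-scores.

Each crypt's mean NDUFB8 (complex I) and MTCO1 (complex IV) intensities
are normalized to the mitochondrial mass marker (TOMM20 by default) and
standardized against the pooled wild-type cohort:

    z = (marker/mass − mean_ref) / sd_ref

A crypt is called deficient in a complex when its z-score falls strictly
below the threshold (−4.5 by default); the four-way category is the
combination of the two calls.  The raw mass markers are z-scored the
same way purely as a QC check — a crypt flagged there would indicate a
mitochondrial mass difference rather than an OXPHOS defect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cryptmosaic.synthetic_cohort import CATEGORIES, MASS_MARKERS, OXPHOS_MARKERS

DEFAULT_THRESHOLD = -4.5

CALL_COLUMNS = [
    "mouse_id",
    "genotype",
    "crypt_id",
    "z_ci",
    "z_civ",
    "z_mass",
    "category",
    "mass_qc_flag",
]


@dataclass
class ReferenceDistribution:
    """Pooled control-cohort moments used for z-scoring.

    ``ratio_mean``/``ratio_sd`` hold, per OXPHOS marker, the mean and
    sample SD (n−1 denominator) of the per-crypt marker/mass ratio over
    every control crypt, pooled across control mice.  ``mass_mean``/
    ``mass_sd`` hold the same for the raw mass-marker intensities.
    """

    ratio_mean: dict[str, float]
    ratio_sd: dict[str, float]
    mass_mean: dict[str, float]
    mass_sd: dict[str, float]
    mass_marker: str = "tomm20"
    log_ratio: bool = False
    n_control_crypts: int = 0

    def validate(self) -> None:
        if self.n_control_crypts < 2:
            raise ValueError("reference needs at least 2 control crypts")
        for name, sd in {**self.ratio_sd, **self.mass_sd}.items():
            if not sd > 0:
                raise ValueError(f"reference SD for {name!r} must be positive")


def _ratios(df: pd.DataFrame, mass_marker: str, log_ratio: bool) -> pd.DataFrame:
    for col in OXPHOS_MARKERS + (mass_marker,):
        if col not in df.columns:
            raise ValueError(f"missing marker column {col!r}")
    mass = df[mass_marker].to_numpy(dtype=float)
    if np.any(mass <= 0):
        raise ValueError(f"non-positive {mass_marker!r} intensity; ratios undefined")
    out = {}
    for m in OXPHOS_MARKERS:
        r = df[m].to_numpy(dtype=float) / mass
        out[m] = np.log(r) if log_ratio else r
    return pd.DataFrame(out, index=df.index)


def build_reference(
    control_records: pd.DataFrame,
    mass_marker: str = "tomm20",
    log_ratio: bool = False,
) -> ReferenceDistribution:
    """Pool all control crypts into a reference distribution.

    The records passed in *are* the control cohort (filter by genotype
    before calling, or use :func:`classify_cohort` which does so).
    """
    n = len(control_records)
    if n < 2:
        raise ValueError("need at least 2 control crypts to estimate a reference SD")
    ratios = _ratios(control_records, mass_marker, log_ratio)
    ratio_mean = {m: float(ratios[m].mean()) for m in OXPHOS_MARKERS}
    ratio_sd = {m: float(ratios[m].std(ddof=1)) for m in OXPHOS_MARKERS}
    mass_mean: dict[str, float] = {}
    mass_sd: dict[str, float] = {}
    for m in MASS_MARKERS:
        if m in control_records.columns:
            x = control_records[m].to_numpy(dtype=float)
            if np.any(x <= 0):
                raise ValueError(f"non-positive {m!r} intensity in control records")
            mass_mean[m] = float(x.mean())
            mass_sd[m] = float(x.std(ddof=1))
    ref = ReferenceDistribution(
        ratio_mean=ratio_mean,
        ratio_sd=ratio_sd,
        mass_mean=mass_mean,
        mass_sd=mass_sd,
        mass_marker=mass_marker,
        log_ratio=log_ratio,
        n_control_crypts=n,
    )
    ref.validate()
    return ref


def score_crypts(records: pd.DataFrame, reference: ReferenceDistribution) -> pd.DataFrame:
    """Attach z_ci, z_civ and z_mass columns to a copy of ``records``.

    z_ci / z_civ standardize the mass-normalized NDUFB8 / MTCO1 level
    against the control reference; z_mass standardizes the raw
    normalization mass marker.
    """
    reference.validate()
    ratios = _ratios(records, reference.mass_marker, reference.log_ratio)
    out = records.copy()
    out["z_ci"] = (ratios["ndufb8"] - reference.ratio_mean["ndufb8"]) / reference.ratio_sd[
        "ndufb8"
    ]
    out["z_civ"] = (ratios["mtco1"] - reference.ratio_mean["mtco1"]) / reference.ratio_sd[
        "mtco1"
    ]
    mm = reference.mass_marker
    out["z_mass"] = (records[mm].to_numpy(dtype=float) - reference.mass_mean[mm]) / reference.mass_sd[mm]
    return out


def classify_crypt(z_ci: float, z_civ: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Four-way category from the two z-scores.

    The comparison is strict (< threshold); a crypt sitting exactly on
    the line is NORMAL.
    """
    if not (np.isfinite(z_ci) and np.isfinite(z_civ)):
        raise ValueError("z-scores must be finite")
    ci = z_ci < threshold
    civ = z_civ < threshold
    if ci and civ:
        return "CI_CIV_DEF"
    if ci:
        return "CI_DEF"
    if civ:
        return "CIV_DEF"
    return "NORMAL"


def classify_crypts(z_ci: np.ndarray, z_civ: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Vectorized :func:`classify_crypt`."""
    z_ci = np.asarray(z_ci, dtype=float)
    z_civ = np.asarray(z_civ, dtype=float)
    if not (np.all(np.isfinite(z_ci)) and np.all(np.isfinite(z_civ))):
        raise ValueError("z-scores must be finite")
    ci = z_ci < threshold
    civ = z_civ < threshold
    out = np.full(z_ci.shape, "NORMAL", dtype=object)
    out[ci & ~civ] = "CI_DEF"
    out[~ci & civ] = "CIV_DEF"
    out[ci & civ] = "CI_CIV_DEF"
    return out


def classify_cohort(
    records: pd.DataFrame,
    reference: ReferenceDistribution | None = None,
    control_genotype: str = "+/+",
    threshold: float = DEFAULT_THRESHOLD,
    mass_marker: str = "tomm20",
    log_ratio: bool = False,
) -> pd.DataFrame:
    """Score and classify every crypt in ``records``.

    If no reference is given, one is built from the ``control_genotype``
    rows of ``records`` itself.  Returns the calls table
    (``CALL_COLUMNS``); ``mass_qc_flag`` is True when the raw mass
    marker itself falls below the threshold.
    """
    if reference is None:
        controls = records[records["genotype"] == control_genotype]
        if controls.empty:
            raise ValueError(
                f"no records with control genotype {control_genotype!r} to build a reference"
            )
        reference = build_reference(controls, mass_marker=mass_marker, log_ratio=log_ratio)
    scored = score_crypts(records, reference)
    scored["category"] = classify_crypts(
        scored["z_ci"].to_numpy(), scored["z_civ"].to_numpy(), threshold
    )
    scored["mass_qc_flag"] = scored["z_mass"].to_numpy() < threshold
    return scored[CALL_COLUMNS]


def per_mouse_percentages(calls: pd.DataFrame) -> pd.DataFrame:
    """Percentage of each mouse's crypts in each category (rows sum to 100)."""
    if calls.empty:
        raise ValueError("empty calls table")
    counts = (
        calls.groupby(["genotype", "mouse_id"])["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct.reset_index()


def summarize_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean and SEM of the per-mouse category percentages.

    SEM is SD(ddof=1)/sqrt(n_mice); with a single mouse it is reported
    as 0 with a warning (rather than NaN) so summaries stay numeric.
    """
    pct = per_mouse_percentages(calls)
    rows = []
    for geno, sub in pct.groupby("genotype", sort=False):
        n_mice = len(sub)
        if n_mice == 1:
            warnings.warn(
                f"genotype {geno!r} has a single mouse; SEM reported as 0",
                stacklevel=2,
            )
        for cat in CATEGORIES:
            vals = sub[cat].to_numpy(dtype=float)
            sem = float(vals.std(ddof=1) / np.sqrt(n_mice)) if n_mice > 1 else 0.0
            rows.append(
                {
                    "genotype": geno,
                    "category": cat,
                    "n_mice": n_mice,
                    "mean_pct": float(vals.mean()),
                    "sem_pct": sem,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MassQCReport:
    """Mass-marker QC: crypts whose raw mass marker z-score is below threshold."""

    flagged: pd.DataFrame
    per_genotype_counts: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def mass_marker_qc(
    records: pd.DataFrame,
    reference: ReferenceDistribution,
    threshold: float = DEFAULT_THRESHOLD,
) -> MassQCReport:
    """Flag crypts deficient in any mass marker the reference knows about.

    An empty report is the expected outcome: OXPHOS deficiency should
    not change mitochondrial mass, so TOMM20 and VDAC1 z-scores should
    never cross the calling line.
    """
    reference.validate()
    flags = []
    for m, mu in reference.mass_mean.items():
        if m not in records.columns:
            continue
        z = (records[m].to_numpy(dtype=float) - mu) / reference.mass_sd[m]
        low = z < threshold
        if np.any(low):
            sub = records.loc[low, ["mouse_id", "genotype", "crypt_id"]].copy()
            sub["mass_marker"] = m
            sub["z"] = z[low]
            flags.append(sub)
    flagged = (
        pd.concat(flags, ignore_index=True)
        if flags
        else pd.DataFrame(columns=["mouse_id", "genotype", "crypt_id", "mass_marker", "z"])
    )
    genotypes = records["genotype"].unique()
    counts = []
    for m in reference.mass_mean:
        if m not in records.columns:
            continue
        for geno in genotypes:
            n = int(((flagged["mass_marker"] == m) & (flagged["genotype"] == geno)).sum())
            counts.append({"genotype": geno, "mass_marker": m, "n_flagged": n})
    return MassQCReport(
        flagged=flagged,
        per_genotype_counts=pd.DataFrame(counts),
        threshold=threshold,
    )
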