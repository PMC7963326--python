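"""Forward simulator of the dual thymidine-analogue labelling protocol.

The emulated experiment injects CldU twice daily for three days and once
on the morning of day four, follows with a single IdU injection that
evening, and sacrifices the animal 15 h later.  A cell incorporates an
analogue when one of its S phases overlaps an availability window
following an injection, so CldU marks cells that divided during the
four-day window, IdU marks cells that divided in the final 15 h, and
CldU+IdU cells divided at least twice.

Cell model
----------
Each cell slot is an independent alternating-renewal process:

* an *active run* of one or more consecutive cell cycles, cycle lengths
  lognormal around ``mean_cycle_time``; after each mitosis the cell
  pauses with probability ``quiescence_rate``, otherwise it re-enters
  the next cycle immediately;
* a *quiescent gap*, exponentially distributed (memoryless re-entry).

The S phase occupies ``s_phase_fraction`` of each cycle, placed after a
G1 taking 60% of the non-S time.  A cell is Ki-67+ when it is inside an
active run at sacrifice.  Labels persist once acquired; there is no
label dilution and no lineage structure — the observables are per-crypt
counts, for which independent slots suffice.

``rate_multiplier`` is the parameter of scientific interest: it scales
the slot's *long-run division rate* (1 = OXPHOS-normal), acting through
the mean quiescent gap.  Because cycle durations are fixed, the gap for
multiplier m is chosen so the stationary division rate is exactly
m times the baseline rate; expected label counts then scale
multiplicatively in m (up to per-cell saturation), which is the
structure the log-link random-intercept GLMM assumes.  A per-mouse
lognormal frailty enters the same way, so the mouse random intercept is
correctly specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLDU = "CldU"
IDU = "IdU"

COUNT_COLUMNS = [
    "mouse_id",
    "group_label",
    "crypt_id",
    "total_cells",
    "ki67",
    "cldu",
    "idu",
    "dual",
    "lgr5_total",
    "lgr5_cldu",
    "lgr5_idu",
    "lgr5_dual",
]

#: hours of the default protocol: CldU at 10am and 6pm on days 1-3 and at
#: 10am on day 4 (hour 0 = 10am day 1), IdU at 6pm on day 4, death 15 h later
DEFAULT_CLDU_HOURS = (0.0, 8.0, 24.0, 32.0, 48.0, 56.0, 72.0)
DEFAULT_IDU_HOUR = 80.0
DEFAULT_SACRIFICE_HOUR = 95.0

#: G1 share of the non-S part of the cycle (remainder is G2+M)
_G1_SHARE = 0.6


@dataclass(frozen=True)
class InjectionSchedule:
    """Timed analogue injections plus the sacrifice time (hours)."""

    events: tuple[tuple[float, str], ...]
    availability_window: float = 2.0
    sacrifice_time: float = DEFAULT_SACRIFICE_HOUR

    def validate(self) -> None:
        if not self.events:
            raise ValueError("schedule must contain at least one injection event")
        times = [t for t, _ in self.events]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("injection events must be strictly increasing in time")
        for _, analogue in self.events:
            if analogue not in (CLDU, IDU):
                raise ValueError(f"unknown analogue {analogue!r}")
        if self.availability_window < 0:
            raise ValueError("availability_window must be nonnegative")
        if self.sacrifice_time <= times[-1]:
            raise ValueError("sacrifice_time must be after the last injection")

    def windows(self, analogue: str) -> np.ndarray:
        """Merged availability intervals for one analogue, clipped at sacrifice.

        Returns an array of shape (k, 2) of [start, end) intervals.
        """
        ivs = [
            (t, min(t + self.availability_window, self.sacrifice_time))
            for t, a in self.events
            if a == analogue
        ]
        ivs = [(a, b) for a, b in ivs if b > a]
        merged: list[list[float]] = []
        for a, b in sorted(ivs):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return np.asarray(merged, dtype=float).reshape(-1, 2)


def build_schedule(
    cldu_hours: Sequence[float] = DEFAULT_CLDU_HOURS,
    idu_hours: Sequence[float] = (DEFAULT_IDU_HOUR,),
    availability_window: float = 2.0,
    sacrifice_time: float = DEFAULT_SACRIFICE_HOUR,
) -> InjectionSchedule:
    """Build a schedule; defaults reproduce the 4-day CldU / single-IdU protocol."""
    events = sorted(
        [(float(t), CLDU) for t in cldu_hours] + [(float(t), IDU) for t in idu_hours]
    )
    sched = InjectionSchedule(
        events=tuple(events),
        availability_window=availability_window,
        sacrifice_time=sacrifice_time,
    )
    sched.validate()
    return sched


@dataclass
class CryptSimParams:
    """Per-crypt cell-population parameters.

    ``n_total_cells`` is the longitudinal-section cell count scale and
    ``n_lgr5_high`` the LGR5-high (stem) subset size.  ``quiescence_rate``
    is the per-mitosis probability of pausing before re-entry and
    ``quiescence_scale_hours`` the mean quiescent gap at multiplier 1;
    together with the 24-h cycle they set the baseline division rate.
    """

    n_total_cells: int = 70
    n_lgr5_high: int = 14
    mean_cycle_time: float = 24.0
    cycle_cv: float = 0.15
    s_phase_fraction: float = 8.0 / 24.0
    quiescence_rate: float = 0.2
    quiescence_scale_hours: float = 600.0
    rate_multiplier: float = 1.0
    group_label: str = "NORMAL"

    def validate(self) -> None:
        if self.n_total_cells < 1:
            raise ValueError("n_total_cells must be a positive integer")
        if self.n_lgr5_high < 1 or self.n_lgr5_high > self.n_total_cells:
            raise ValueError("n_lgr5_high must lie in [1, n_total_cells]")
        if self.mean_cycle_time <= 0:
            raise ValueError("mean_cycle_time must be positive")
        if self.cycle_cv < 0:
            raise ValueError("cycle_cv must be nonnegative")
        if not 0.0 < self.s_phase_fraction < 1.0:
            raise ValueError("s_phase_fraction must lie in (0, 1)")
        if not 0.0 <= self.quiescence_rate <= 1.0:
            raise ValueError("quiescence_rate must lie in [0, 1]")
        if self.quiescence_scale_hours <= 0:
            raise ValueError("quiescence_scale_hours must be positive")
        if self.rate_multiplier < 0:
            raise ValueError("rate_multiplier must be nonnegative")
        if self.quiescence_rate > 0 and self.rate_multiplier > 0:
            # gap(m) must stay positive: the division rate cannot exceed
            # the continuous-cycling bound 1/mean_cycle_time
            m_max = 1.0 + self.quiescence_rate * self.quiescence_scale_hours / self.mean_cycle_time
            if self.rate_multiplier >= m_max:
                raise ValueError(
                    f"rate_multiplier must be < {m_max:.3g} for this quiescence scale"
                )

    def gap_mean(self, multiplier: float | np.ndarray) -> np.ndarray:
        """Mean quiescent gap realizing a division rate of ``multiplier`` × baseline.

        Division rate for gap g is 1/(C + q·g) with C the mean cycle and
        q the pause probability; solving D(m) = m·D(1) for g gives
        g(m) = ((C + q·g0)/m − C)/q.  multiplier 0 maps to an infinite
        gap (permanent quiescence once paused).
        """
        m = np.asarray(multiplier, dtype=float)
        c, q, g0 = self.mean_cycle_time, self.quiescence_rate, self.quiescence_scale_hours
        if q == 0:
            return np.full_like(m, np.inf)
        with np.errstate(divide="ignore", over="ignore"):
            g = ((c + q * g0) / m - c) / q
        if np.any(g <= 0):
            raise ValueError("rate_multiplier (including frailty) too large for quiescence scale")
        return g


@dataclass
class LabelCountRecord:
    """Per-crypt label counts (whole crypt and LGR5-high subset)."""

    mouse_id: str
    crypt_id: str
    group_label: str
    total_cells: int
    ki67_pos: int
    cldu_pos: int
    idu_pos: int
    dual_pos: int
    lgr5_total: int
    lgr5_cldu: int
    lgr5_idu: int
    lgr5_dual: int

    def validate(self) -> None:
        counts = [
            self.total_cells,
            self.ki67_pos,
            self.cldu_pos,
            self.idu_pos,
            self.dual_pos,
            self.lgr5_total,
            self.lgr5_cldu,
            self.lgr5_idu,
            self.lgr5_dual,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if self.dual_pos > min(self.cldu_pos, self.idu_pos):
            raise ValueError("dual_pos must not exceed min(cldu_pos, idu_pos)")
        for c in (self.ki67_pos, self.cldu_pos, self.idu_pos, self.dual_pos):
            if c > self.total_cells:
                raise ValueError("label counts must not exceed total_cells")
        if self.lgr5_total > self.total_cells:
            raise ValueError("lgr5_total must not exceed total_cells")
        for c in (self.lgr5_cldu, self.lgr5_idu, self.lgr5_dual):
            if c > self.lgr5_total:
                raise ValueError("LGR5 label counts must not exceed lgr5_total")
        if self.lgr5_dual > min(self.lgr5_cldu, self.lgr5_idu):
            raise ValueError("lgr5_dual must not exceed min(lgr5_cldu, lgr5_idu)")


def _simulate_slots(
    n: int,
    params: CryptSimParams,
    schedule: InjectionSchedule,
    rng: np.random.Generator,
    gap_means: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Simulate ``n`` independent cell slots; returns boolean label arrays.

    ``gap_means`` optionally gives a per-slot mean quiescent gap
    (already including any multiplier/frailty); by default it comes from
    ``params.rate_multiplier``.
    """
    schedule.validate()
    end = schedule.sacrifice_time
    cw = schedule.windows(CLDU)
    iw = schedule.windows(IDU)
    c, q, cv = params.mean_cycle_time, params.quiescence_rate, params.cycle_cv
    sfrac = params.s_phase_fraction
    g1frac = _G1_SHARE * (1.0 - sfrac)
    sigma2 = math.log1p(cv * cv)
    mu, sigma = math.log(c) - 0.5 * sigma2, math.sqrt(sigma2)

    cldu = np.zeros(n, dtype=bool)
    idu = np.zeros(n, dtype=bool)
    ki67 = np.zeros(n, dtype=bool)

    # Stationary start, exactly: because pausing is Bernoulli per completed
    # cycle and gaps are exponential, a cell's future depends only on whether
    # it is currently cycling (probability = duty fraction) — mid-cycle at a
    # uniform phase — or quiescent, with a memoryless remaining gap.
    origin = min(0.0, min(tt for tt, _ in schedule.events))
    if q > 0:
        if gap_means is None:
            gap_means = params.gap_mean(np.full(n, params.rate_multiplier))
        gap_means = np.broadcast_to(np.asarray(gap_means, dtype=float), (n,)).copy()
        mean_run = c / q
        with np.errstate(invalid="ignore"):
            duty = np.where(
                np.isfinite(gap_means), mean_run / (mean_run + gap_means), 0.0
            )
        cycling = rng.random(n) < duty
        t = np.where(cycling, origin - rng.uniform(0.0, c, size=n), origin)
        in_gap = ~cycling
    else:
        # continuous cycling: every cell mid-cycle at a uniform phase
        t = origin - rng.uniform(0.0, c, size=n)
        in_gap = np.zeros(n, dtype=bool)
        gap_means = np.full(n, np.inf)

    for _ in range(100_000):
        if not (t <= end).any():
            break
        g_idx = np.flatnonzero((t <= end) & in_gap)
        if g_idx.size:
            gm = gap_means[g_idx]
            finite = np.isfinite(gm)
            step = np.full(g_idx.size, np.inf)
            if finite.any():
                step[finite] = rng.exponential(gm[finite])
            t[g_idx] = t[g_idx] + step
            in_gap[g_idx] = False
        # recompute: a gap may have jumped past sacrifice this iteration
        c_idx = np.flatnonzero((t <= end) & ~in_gap)
        if c_idx.size:
            ln = rng.lognormal(mu, sigma, size=c_idx.size)
            t0 = t[c_idx]
            s0 = t0 + g1frac * ln
            s1 = s0 + sfrac * ln
            if cw.size:
                cldu[c_idx] |= ((s0[:, None] < cw[:, 1]) & (s1[:, None] > cw[:, 0])).any(axis=1)
            if iw.size:
                idu[c_idx] |= ((s0[:, None] < iw[:, 1]) & (s1[:, None] > iw[:, 0])).any(axis=1)
            ki67[c_idx] |= t0 + ln > end
            t[c_idx] = t0 + ln
            if q > 0:
                in_gap[c_idx] = rng.random(c_idx.size) < q
    else:  # pragma: no cover - defensive
        raise RuntimeError("cell-slot simulation did not terminate")

    return {"cldu": cldu, "idu": idu, "dual": cldu & idu, "ki67": ki67}


def simulate_crypt(
    params: CryptSimParams,
    schedule: InjectionSchedule | None = None,
    rng: np.random.Generator | None = None,
    mouse_id: str = "m1",
    crypt_id: str = "c1",
    mouse_multiplier: float = 1.0,
) -> LabelCountRecord:
    """Simulate one crypt and return its label-count record.

    The first ``n_lgr5_high`` slots form the LGR5-high subset; all slots
    share the crypt's cycling parameters.  ``mouse_multiplier`` is the
    mouse-level frailty on the division rate.
    """
    params.validate()
    if schedule is None:
        schedule = build_schedule()
    if rng is None:
        rng = np.random.default_rng()
    n = params.n_total_cells
    eff = params.rate_multiplier * mouse_multiplier
    gaps = params.gap_mean(np.full(n, eff)) if params.quiescence_rate > 0 else None
    res = _simulate_slots(n, params, schedule, rng, gap_means=gaps)
    k = params.n_lgr5_high
    rec = LabelCountRecord(
        mouse_id=mouse_id,
        crypt_id=crypt_id,
        group_label=params.group_label,
        total_cells=n,
        ki67_pos=int(res["ki67"].sum()),
        cldu_pos=int(res["cldu"].sum()),
        idu_pos=int(res["idu"].sum()),
        dual_pos=int(res["dual"].sum()),
        lgr5_total=k,
        lgr5_cldu=int(res["cldu"][:k].sum()),
        lgr5_idu=int(res["idu"][:k].sum()),
        lgr5_dual=int(res["dual"][:k].sum()),
    )
    rec.validate()
    return rec


@dataclass
class CohortConfig:
    """Cohort layout: group parameters, crypt totals, mice and frailty."""

    group_params: Mapping[str, CryptSimParams]
    crypts_per_group: Mapping[str, int]
    n_mice: int = 4
    mouse_frailty_sd: float = 0.0
    shared_mice: bool = True
    vary_cell_counts: bool = True
    seed: int = 0


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Four-category intra-mouse cohort with the emulated study's crypt counts.

    286 crypts over 4 shared mice: 100 OXPHOS-normal, 117 CI-deficient,
    35 CIV-deficient and 34 CI+CIV-deficient, with division-rate
    multipliers emulating the reported pattern (CI-driven ~20% increase,
    slowed cycle re-entry under isolated CIV deficiency).
    """
    mults = {"NORMAL": 1.0, "CI_DEF": 1.2, "CIV_DEF": 0.8, "CI_CIV_DEF": 1.2}
    params = {
        g: replace(CryptSimParams(), rate_multiplier=m, group_label=g)
        for g, m in mults.items()
    }
    crypts = {"NORMAL": 100, "CI_DEF": 117, "CIV_DEF": 35, "CI_CIV_DEF": 34}
    return CohortConfig(group_params=params, crypts_per_group=crypts, seed=seed)


def _split(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def simulate_label_cohort(
    config: CohortConfig,
    schedule: InjectionSchedule | None = None,
) -> pd.DataFrame:
    """Simulate a whole cohort of crypts; returns the counts table.

    With ``shared_mice`` the same mice contribute crypts to every group
    (the intra-mouse mosaic design); otherwise each group has its own
    mice.  A lognormal mouse frailty multiplies the division rate of all
    of a mouse's cells, which is exactly the random intercept the GLMM
    estimates on the log scale.
    """
    if schedule is None:
        schedule = build_schedule()
    if config.n_mice < 1:
        raise ValueError("n_mice must be at least 1")
    if config.mouse_frailty_sd < 0:
        raise ValueError("mouse_frailty_sd must be nonnegative")
    for label, p in config.group_params.items():
        p.validate()
        if label not in config.crypts_per_group:
            raise ValueError(f"crypts_per_group is missing group {label!r}")
        if config.crypts_per_group[label] < 1:
            raise ValueError(f"crypts_per_group[{label!r}] must be positive")

    rng = np.random.default_rng(config.seed)
    groups = list(config.group_params)
    if config.shared_mice:
        mice = {g: [f"m{i + 1}" for i in range(config.n_mice)] for g in groups}
        frailty_by_mouse = {
            f"m{i + 1}": (
                rng.lognormal(0.0, config.mouse_frailty_sd)
                if config.mouse_frailty_sd > 0
                else 1.0
            )
            for i in range(config.n_mice)
        }
    else:
        mice = {g: [f"{g}_m{i + 1}" for i in range(config.n_mice)] for g in groups}
        frailty_by_mouse = {
            mid: (
                rng.lognormal(0.0, config.mouse_frailty_sd)
                if config.mouse_frailty_sd > 0
                else 1.0
            )
            for g in groups
            for mid in mice[g]
        }

    rows: list[dict] = []
    for g in groups:
        params = config.group_params[g]
        alloc = _split(config.crypts_per_group[g], config.n_mice)
        for mouse, n_crypts in zip(mice[g], alloc):
            if n_crypts == 0:
                continue
            if config.vary_cell_counts:
                totals = np.maximum(rng.poisson(params.n_total_cells, n_crypts), 2)
                lgr5 = np.clip(rng.poisson(params.n_lgr5_high, n_crypts), 1, totals)
            else:
                totals = np.full(n_crypts, params.n_total_cells)
                lgr5 = np.full(n_crypts, params.n_lgr5_high)
            n_cells = int(totals.sum())
            crypt_of_cell = np.repeat(np.arange(n_crypts), totals)
            start = np.concatenate(([0], np.cumsum(totals)[:-1]))
            within = np.arange(n_cells) - np.repeat(start, totals)
            is_lgr5 = within < np.repeat(lgr5, totals)

            eff = params.rate_multiplier * frailty_by_mouse[mouse]
            gaps = (
                params.gap_mean(np.full(n_cells, eff))
                if params.quiescence_rate > 0
                else None
            )
            res = _simulate_slots(n_cells, params, schedule, rng, gap_means=gaps)

            def crypt_sum(mask: np.ndarray) -> np.ndarray:
                return np.bincount(crypt_of_cell[mask], minlength=n_crypts).astype(int)

            agg = {
                "ki67": crypt_sum(res["ki67"]),
                "cldu": crypt_sum(res["cldu"]),
                "idu": crypt_sum(res["idu"]),
                "dual": crypt_sum(res["dual"]),
                "lgr5_cldu": crypt_sum(res["cldu"] & is_lgr5),
                "lgr5_idu": crypt_sum(res["idu"] & is_lgr5),
                "lgr5_dual": crypt_sum(res["dual"] & is_lgr5),
            }
            for j in range(n_crypts):
                rows.append(
                    {
                        "mouse_id": mouse,
                        "group_label": g,
                        "crypt_id": f"{g}-c{j + 1:04d}",
                        "total_cells": int(totals[j]),
                        "ki67": int(agg["ki67"][j]),
                        "cldu": int(agg["cldu"][j]),
                        "idu": int(agg["idu"][j]),
                        "dual": int(agg["dual"][j]),
                        "lgr5_total": int(lgr5[j]),
                        "lgr5_cldu": int(agg["lgr5_cldu"][j]),
                        "lgr5_idu": int(agg["lgr5_idu"][j]),
                        "lgr5_dual": int(agg["lgr5_dual"][j]),
                    }
                )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def simulate_counts_for_crypts(
    crypt_table: pd.DataFrame,
    params_by_category: Mapping[str, CryptSimParams],
    schedule: InjectionSchedule | None = None,
    mouse_frailty_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate label counts for a fixed set of crypts with known categories.

    ``crypt_table`` needs columns ``mouse_id, crypt_id, category``; the
    output keeps those keys so it joins back onto classifier calls.
    Used by the pipeline to emulate the serial-section design, where the
    same crypt is scored for OXPHOS status and for label counts.
    """
    if schedule is None:
        schedule = build_schedule()
    required = {"mouse_id", "crypt_id", "category"}
    missing = required - set(crypt_table.columns)
    if missing:
        raise ValueError(f"crypt_table is missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    frailty = {
        m: rng.lognormal(0.0, mouse_frailty_sd) if mouse_frailty_sd > 0 else 1.0
        for m in crypt_table["mouse_id"].unique()
    }
    rows = []
    for (mouse, cat), sub in crypt_table.groupby(["mouse_id", "category"], sort=False):
        if cat not in params_by_category:
            raise ValueError(f"no simulation parameters for category {cat!r}")
        params = params_by_category[cat]
        params.validate()
        n_crypts = len(sub)
        totals = np.maximum(rng.poisson(params.n_total_cells, n_crypts), 2)
        lgr5 = np.clip(rng.poisson(params.n_lgr5_high, n_crypts), 1, totals)
        n_cells = int(totals.sum())
        crypt_of_cell = np.repeat(np.arange(n_crypts), totals)
        start = np.concatenate(([0], np.cumsum(totals)[:-1]))
        is_lgr5 = (np.arange(n_cells) - np.repeat(start, totals)) < np.repeat(lgr5, totals)
        eff = params.rate_multiplier * frailty[mouse]
        gaps = (
            params.gap_mean(np.full(n_cells, eff))
            if params.quiescence_rate > 0
            else None
        )
        res = _simulate_slots(n_cells, params, schedule, rng, gap_means=gaps)
        agg = {
            name: np.bincount(crypt_of_cell[mask], minlength=n_crypts)
            for name, mask in (
                ("ki67", res["ki67"]),
                ("cldu", res["cldu"]),
                ("idu", res["idu"]),
                ("dual", res["dual"]),
                ("lgr5_cldu", res["cldu"] & is_lgr5),
                ("lgr5_idu", res["idu"] & is_lgr5),
                ("lgr5_dual", res["dual"] & is_lgr5),
            )
        }
        for j, (_, crypt_row) in enumerate(sub.iterrows()):
            rows.append(
                {
                    "mouse_id": mouse,
                    "group_label": cat,
                    "crypt_id": crypt_row["crypt_id"],
                    "total_cells": int(totals[j]),
                    "ki67": int(agg["ki67"][j]),
                    "cldu": int(agg["cldu"][j]),
                    "idu": int(agg["idu"][j]),
                    "dual": int(agg["dual"][j]),
                    "lgr5_total": int(lgr5[j]),
                    "lgr5_cldu": int(agg["lgr5_cldu"][j]),
                    "lgr5_idu": int(agg["lgr5_idu"][j]),
                    "lgr5_dual": int(agg["lgr5_dual"][j]),
                }
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)
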