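"""Simultaneous nonlinear least-squares fitting of the trafficking model.

``MigrationModel`` is built from a tidy :class:`~dcflux.datasets.TimeCourseDataset`
and a :class:`ModelSpec`; ``fit`` returns a :class:`MigrationResults` carrying
estimates, fit statistics, AIC and bootstrap confidence intervals.

The objective is least squares on the log scale,
``sum [ln(count + c) - ln(prediction + c)]^2`` with a stabilising offset of
``c = 1`` cell, fitted simultaneously to skin and dLN counts across both
conditions and all photoswitching strategies. Rate and time parameters are
optimised on the natural-log scale (positivity by construction) with
multi-start Nelder-Mead. Under the free-x0 policy the per-strategy initial
pool sizes are separable and are concentrated out of the objective by an
inner Newton solve, so the outer search runs only over the shared kinetic
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datasets import TimeCourseDataset
from .kinetics import _UW, _UX
from .parameters import Condition, RateParameters
from .summaries import KineticSummary

__all__ = ["ModelSpec", "OptimizerSettings", "MigrationModel", "MigrationResults"]

#: stabilising offset (cells) added inside the log residuals
LOG_OFFSET = 1.0

_PENALTY = 1e12

#: a dataset with no dLN observation earlier than this lead time (hours after
#: photoconversion) cannot pin down the transit delay tau
TAU_IDENT_LEAD = 12.0


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model in the AIC family.

    ``*_rate_form`` chooses a constant migration hazard (``mu0``) or the
    inflammatory pulse (``mu0 + alpha t exp(-m t)``) per condition;
    ``delta_shared`` ties the dLN loss rate across conditions; ``x0_policy``
    either fits one free photoconverted pool per (condition, photoconversion
    time) strategy or derives pools from a fitted recruitment curve.
    """

    alum_rate_form: str = "pulse"
    saline_rate_form: str = "constant"
    delta_shared: bool = False
    x0_policy: str = "free-per-design"
    name: str = ""

    def __post_init__(self) -> None:
        for form in (self.alum_rate_form, self.saline_rate_form):
            if form not in ("constant", "pulse"):
                raise ValueError(f"rate form must be constant|pulse, got {form!r}")
        if self.x0_policy not in ("free-per-design", "from-recruitment-curve"):
            raise ValueError(f"unknown x0 policy {self.x0_policy!r}")
        if not self.name:
            label = (
                f"{self.alum_rate_form}-alum/{self.saline_rate_form}-saline/"
                f"{'shared' if self.delta_shared else 'split'}-delta"
            )
            object.__setattr__(self, "name", label)

    @property
    def has_pulse(self) -> bool:
        return "pulse" in (self.alum_rate_form, self.saline_rate_form)

    def rate_param_names(self) -> list[str]:
        names = ["mu0"]
        if self.has_pulse:
            names += ["alpha", "m"]
        names.append("tau")
        names += ["delta"] if self.delta_shared else ["delta_alum", "delta_saline"]
        if self.x0_policy == "from-recruitment-curve":
            names += ["r0", "beta", "b"]
        return names

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if every fit of this spec is reachable by ``other``."""

        def form_ok(a: str, b: str) -> bool:
            return a == b or (a == "constant" and b == "pulse")

        return (
            form_ok(self.alum_rate_form, other.alum_rate_form)
            and form_ok(self.saline_rate_form, other.saline_rate_form)
            and (other.delta_shared in (self.delta_shared, False))
            and self.x0_policy == other.x0_policy
        )


@dataclass(frozen=True)
class OptimizerSettings:
    """Multi-start Nelder-Mead settings; identical settings + seed give an
    identical fit."""

    n_starts: int = 20
    max_iterations: int = 5000
    rel_tol: float = 1e-10
    x_tol: float = 1e-6
    seed: int = 0
    spread_decades: float = 1.5


def _pulse_hazard_integral(alpha, m, t1, t2):
    """int_t1^t2 alpha s e^{-m s} ds, vectorised (m > 0).

    For m*t2 << 1 the closed form cancels catastrophically, so a second-order
    series takes over; the result is clipped at 0 (the true integral is
    non-negative for t2 >= t1).
    """
    closed = (alpha / m**2) * (
        (1.0 + m * t1) * np.exp(-m * t1) - (1.0 + m * t2) * np.exp(-m * t2)
    )
    series = alpha * (
        0.5 * (t2**2 - t1**2) - (m / 3.0) * (t2**3 - t1**3)
    )
    return np.maximum(np.where(m * t2 < 1e-4, series, closed), 0.0)


class MigrationModel:
    """Expected-value trafficking model bound to one dataset and one spec."""

    def __init__(self, dataset: TimeCourseDataset, spec: ModelSpec | None = None):
        self.dataset = dataset
        self.spec = spec or ModelSpec()
        self._build_structure()

    # ------------------------------------------------------------------
    def _build_structure(self) -> None:
        df = self.dataset.frame
        a = np.log(df["count"].to_numpy(dtype=float) + LOG_OFFSET)
        cells = df.assign(_a=a).groupby(
            ["condition", "t_pc", "site", "t_harvest"], sort=True
        )["_a"].agg(["count", "sum", lambda v: float(np.sum(np.square(v)))])
        cells.columns = ["n", "S", "Q"]
        cells = cells.reset_index()
        self._cells = cells
        self._cell_n = cells["n"].to_numpy(dtype=float)
        self._cell_S = cells["S"].to_numpy(dtype=float)
        self._cell_Q = cells["Q"].to_numpy(dtype=float)
        self._cell_alum = (cells["condition"] == Condition.ALUM.value).to_numpy()
        self._cell_tpc = cells["t_pc"].to_numpy(dtype=float)
        self._cell_t = cells["t_harvest"].to_numpy(dtype=float)
        self._cell_skin = (cells["site"] == "skin").to_numpy()
        # x0 groups: one photoconverted pool per (condition, t_pc) strategy
        groups = (
            cells[["condition", "t_pc"]]
            .drop_duplicates()
            .sort_values(["condition", "t_pc"])
            .reset_index(drop=True)
        )
        key = list(zip(groups["condition"], groups["t_pc"]))
        index = {k: i for i, k in enumerate(key)}
        self.group_keys = [f"{c}:tpc{t:g}" for c, t in key]
        self._group_alum = np.array([c == "alum" for c, _ in key])
        self._group_tpc = np.array([t for _, t in key], dtype=float)
        self._cell_group = np.array(
            [index[(c, t)] for c, t in zip(cells["condition"], cells["t_pc"])]
        )
        self.n_groups = len(self.group_keys)
        self.n_obs = int(self._cell_n.sum())
        self.n_params = len(self.spec.rate_param_names()) + (
            self.n_groups if self.spec.x0_policy == "free-per-design" else 0
        )
        if self.n_obs <= self.n_params + 1:
            raise ValueError(
                f"dataset has {self.n_obs} observations but the model needs more "
                f"than {self.n_params + 1}"
            )
        self.tau_weakly_identified = bool(
            np.min(
                self._cell_t[~self._cell_skin] - self._cell_tpc[~self._cell_skin],
                initial=np.inf,
            )
            >= TAU_IDENT_LEAD
        )

    # ------------------------------------------------------------------
    def _decode(self, theta: np.ndarray) -> dict[str, float]:
        names = self.spec.rate_param_names()
        values = np.exp(np.clip(np.asarray(theta, dtype=float), -60.0, 60.0))
        return dict(zip(names, values))

    def _unit_predictions(self, rates: dict[str, float]) -> np.ndarray:
        """Expected counts per cell for unit x0."""
        mu0 = rates["mu0"]
        tau = rates["tau"]
        alpha = rates.get("alpha", 0.0)
        m = rates.get("m", 1.0)
        d_alum = rates.get("delta", rates.get("delta_alum"))
        d_saline = rates.get("delta", rates.get("delta_saline"))
        alum_pulse = self.spec.alum_rate_form == "pulse"
        saline_pulse = self.spec.saline_rate_form == "pulse"
        cell_alpha = np.where(
            self._cell_alum,
            alpha if alum_pulse else 0.0,
            alpha if saline_pulse else 0.0,
        )
        cell_delta = np.where(self._cell_alum, d_alum, d_saline)
        preds = np.empty(len(self._cell_n))

        skin = self._cell_skin
        t1, t2 = self._cell_tpc[skin], self._cell_t[skin]
        hazard = mu0 * (t2 - t1)
        ca = cell_alpha[skin]
        if np.any(ca > 0):
            hazard = hazard + _pulse_hazard_integral(ca, m, t1, t2)
        preds[skin] = np.exp(-hazard)

        dln = ~skin
        t_pc, t = self._cell_tpc[dln], self._cell_t[dln]
        u = np.maximum(0.0, t - tau - t_pc)
        s = t_pc[:, None] + u[:, None] * _UX[None, :]
        haz = mu0 * (s - t_pc[:, None])
        ca = cell_alpha[dln]
        if np.any(ca > 0):
            haz = haz + _pulse_hazard_integral(ca[:, None], m, t_pc[:, None], s)
        rate = mu0 + ca[:, None] * s * np.exp(-m * s)
        age = t[:, None] - tau - s
        # genuine exponents are <= 0 (age >= 0 on the domain); the clip only
        # affects zero-span rows, whose contribution is nulled by u = 0
        expo = np.minimum(-haz - cell_delta[dln][:, None] * age, 0.0)
        preds[dln] = u * ((rate * np.exp(expo)) @ _UW)
        return preds

    # ------------------------------------------------------------------
    def _profile_x0(self, s: np.ndarray, n_iter: int = 8) -> np.ndarray:
        """Concentrated log-x0 per group minimising the log-scale RSS."""
        c = LOG_OFFSET
        n, S = self._cell_n, self._cell_S
        g = self._cell_group
        # init: ignore the offset where predictions are informative
        pos = s > max(s.max(), 1e-300) * 1e-12
        num = np.bincount(
            g[pos], weights=S[pos] - n[pos] * np.log(s[pos] + 1e-300),
            minlength=self.n_groups,
        )
        den = np.bincount(g[pos], weights=n[pos], minlength=self.n_groups)
        v = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
        for _ in range(n_iter):
            p = s * np.exp(v[g])
            L = np.log(p + c)
            w = p / (p + c)
            r = n * L - S
            grad = 2.0 * np.bincount(g, weights=r * w, minlength=self.n_groups)
            hess = 2.0 * np.bincount(
                g, weights=n * w**2 + r * w * (1.0 - w), minlength=self.n_groups
            )
            step = grad / np.maximum(hess, 1e-12)
            v = v - np.clip(step, -5.0, 5.0)
        return v

    def _loss_from_predictions(self, preds: np.ndarray) -> float:
        L = np.log(preds + LOG_OFFSET)
        loss = float(
            np.sum(self._cell_n * L**2 - 2.0 * self._cell_S * L + self._cell_Q)
        )
        # the cell-statistics form can round to a tiny negative at a perfect fit
        return max(loss, 0.0)

    def _group_x0(self, rates: dict[str, float], s: np.ndarray) -> np.ndarray:
        if self.spec.x0_policy == "from-recruitment-curve":
            r0, beta, b = rates["r0"], rates["beta"], rates["b"]
            pool = r0 + np.where(
                self._group_alum,
                beta * self._group_tpc * np.exp(-b * self._group_tpc),
                0.0,
            )
            return pool
        return np.exp(self._profile_x0(s))

    def _objective(self, theta: np.ndarray) -> float:
        rates = self._decode(theta)
        s = self._unit_predictions(rates)
        if not np.all(np.isfinite(s)):
            return _PENALTY
        x0 = self._group_x0(rates, s)
        loss = self._loss_from_predictions(x0[self._cell_group] * s)
        if not math.isfinite(loss):
            return _PENALTY
        return loss

    # ------------------------------------------------------------------
    def residual_loss(self, theta_full: np.ndarray) -> float:
        """Log-scale residual sum of squares at a full transformed vector.

        Layout: the ModelSpec's rate parameters (natural log), followed — under
        the free-x0 policy — by log x0 for each (condition, t_pc) group in
        ``group_keys`` order. Non-finite predictions yield a large finite
        penalty rather than an exception.
        """
        theta_full = np.asarray(theta_full, dtype=float)
        k_rates = len(self.spec.rate_param_names())
        expected = k_rates + (
            self.n_groups if self.spec.x0_policy == "free-per-design" else 0
        )
        if theta_full.shape != (expected,):
            raise ValueError(f"expected parameter vector of length {expected}")
        rates = self._decode(theta_full[:k_rates])
        s = self._unit_predictions(rates)
        if not np.all(np.isfinite(s)):
            return _PENALTY
        if self.spec.x0_policy == "free-per-design":
            x0 = np.exp(theta_full[k_rates:])
        else:
            x0 = self._group_x0(rates, s)
        loss = self._loss_from_predictions(x0[self._cell_group] * s)
        return loss if math.isfinite(loss) else _PENALTY

    # ------------------------------------------------------------------
    def _heuristic_start(self) -> np.ndarray:
        """Moment-based initial guesses from the data themselves."""
        cells = self._cells
        mean_a = self._cell_S / self._cell_n  # mean log(count+1) per cell

        def slope(t, y):
            if len(t) < 2 or np.ptp(t) == 0:
                return np.nan
            return np.polyfit(t, y, 1)[0]

        # mu0: pooled within-strategy slope of saline skin decay
        sk = self._cell_skin & ~self._cell_alum
        slopes = []
        for gid in np.unique(self._cell_group[sk]):
            idx = sk & (self._cell_group == gid)
            s_val = slope(self._cell_t[idx], mean_a[idx])
            if np.isfinite(s_val):
                slopes.append(-s_val)
        mu0 = float(np.clip(np.nanmedian(slopes) if slopes else 0.01, 1e-4, 0.5))

        # delta per condition: late-time slope of dLN decay
        deltas = {}
        for cond, is_alum in (("alum", True), ("saline", False)):
            dl = ~self._cell_skin & (self._cell_alum == is_alum)
            vals = []
            for gid in np.unique(self._cell_group[dl]):
                idx = dl & (self._cell_group == gid)
                t, y = self._cell_t[idx], mean_a[idx]
                if len(t) >= 3:
                    late = t >= np.median(t)
                    s_val = slope(t[late], y[late])
                    if np.isfinite(s_val):
                        vals.append(-s_val)
            deltas[cond] = float(np.clip(np.nanmedian(vals) if vals else 0.1, 0.02, 2.0))

        dl_all = ~self._cell_skin
        lead = np.min(self._cell_t[dl_all] - self._cell_tpc[dl_all], initial=24.0)
        tau = float(np.clip(lead / 4.0, 0.3, 8.0))

        start = {"mu0": mu0, "tau": tau}
        if self.spec.has_pulse:
            m = 1.0 / 24.0
            alum_dln = dl_all & self._cell_alum
            sal_dln = dl_all & ~self._cell_alum
            if alum_dln.any() and sal_dln.any():
                fold = np.exp(np.max(mean_a[alum_dln]) - np.max(mean_a[sal_dln]))
            else:
                fold = 10.0
            fold = float(np.clip(fold, 2.0, 50.0))
            start["alpha"] = (fold - 1.0) * mu0 * m * math.e
            start["m"] = m
        if self.spec.delta_shared:
            start["delta"] = 0.5 * (deltas["alum"] + deltas["saline"])
        else:
            start["delta_alum"] = deltas["alum"]
            start["delta_saline"] = deltas["saline"]
        if self.spec.x0_policy == "from-recruitment-curve":
            sal_skin = self._cell_skin & ~self._cell_alum
            r0 = float(np.exp(np.max(mean_a[sal_skin], initial=math.log(100.0))))
            start["r0"] = max(r0, 1.0)
            start["beta"] = max(r0, 1.0) * math.e / 18.0
            start["b"] = 1.0 / 18.0
        names = self.spec.rate_param_names()
        _ = cells  # cells retained for debugging
        return np.log([start[name] for name in names])

    def fit(
        self,
        settings: OptimizerSettings | None = None,
        extra_starts: list[np.ndarray] | None = None,
    ) -> "MigrationResults":
        """Best of ``n_starts`` Nelder-Mead runs from dispersed log-scale
        starting points (plus any caller-supplied warm starts)."""
        settings = settings or OptimizerSettings()
        rng = np.random.default_rng(settings.seed)
        base = self._heuristic_start()
        starts = [base]
        spread = settings.spread_decades * math.log(10.0)
        for _ in range(max(0, settings.n_starts - 1)):
            starts.append(base + rng.uniform(-spread, spread, size=base.size))
        for extra in extra_starts or []:
            starts.append(np.asarray(extra, dtype=float))

        best: tuple[float, tuple, np.ndarray, bool] | None = None
        start_losses, nfev = [], 0
        for x0 in starts:
            res = minimize(
                self._objective,
                x0,
                method="Nelder-Mead",
                options={
                    "maxiter": settings.max_iterations,
                    "maxfev": settings.max_iterations,
                    "fatol": settings.rel_tol,
                    "xatol": settings.x_tol,
                },
            )
            nfev += res.nfev
            start_losses.append((self._objective(x0), float(res.fun)))
            key = (float(res.fun), tuple(np.round(res.x, 12)), res.x, bool(res.success))
            # deterministic tie-break: smallest loss, then lexicographically
            # smallest log-parameter vector
            if best is None or key[0] < best[0] * (1 - 1e-9) - 1e-12:
                best = key
            elif abs(key[0] - best[0]) <= 1e-9 * max(1.0, best[0]) and key[1] < best[1]:
                best = key
        assert best is not None
        loss, _, theta, converged_best = best
        if not converged_best:
            # the winning run ended on the iteration cap: polish with one
            # restarted simplex from its endpoint
            res = minimize(
                self._objective,
                theta,
                method="Nelder-Mead",
                options={
                    "maxiter": settings.max_iterations,
                    "maxfev": settings.max_iterations,
                    "fatol": settings.rel_tol,
                    "xatol": settings.x_tol,
                },
            )
            nfev += res.nfev
            if res.fun <= loss:
                loss, theta, converged_best = float(res.fun), res.x, bool(res.success)
        rates = self._decode(theta)
        s = self._unit_predictions(rates)
        x0_groups = self._group_x0(rates, s)
        return MigrationResults(
            model=self,
            spec=self.spec,
            settings=settings,
            theta=np.asarray(theta, dtype=float),
            rates=rates,
            x0_groups=dict(zip(self.group_keys, x0_groups.tolist())),
            rss=float(loss),
            converged=converged_best,
            start_losses=start_losses,
            n_function_evals=nfev,
        )


@dataclass
class MigrationResults:
    """Fitted trafficking model: estimates, diagnostics and summaries."""

    model: MigrationModel = field(repr=False)
    spec: ModelSpec
    settings: OptimizerSettings
    theta: np.ndarray = field(repr=False)
    rates: dict[str, float]
    x0_groups: dict[str, float]
    rss: float
    converged: bool
    start_losses: list[tuple[float, float]] = field(repr=False)
    n_function_evals: int = 0
    bootstrap_intervals: dict[str, tuple[float, float]] | None = None

    # -- derived ------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def aic(self) -> float:
        from .selection import aic

        return aic(self.rss, self.n_obs, self.n_params)

    @property
    def tau_weakly_identified(self) -> bool:
        return self.model.tau_weakly_identified

    @property
    def params(self) -> RateParameters:
        r = self.rates
        return RateParameters(
            mu0=r["mu0"],
            alpha=r.get("alpha", 0.0) if self.spec.alum_rate_form == "pulse" else 0.0,
            m=r.get("m", 0.0) if self.spec.has_pulse else 0.0,
            tau=r["tau"],
            delta_alum=r.get("delta", r.get("delta_alum")),
            delta_saline=r.get("delta", r.get("delta_saline")),
        )

    def x0_for_design(self, design) -> float:
        key = f"{Condition.coerce(design.condition).value}:tpc{design.t_pc:g}"
        return self.x0_groups[key]

    def kinetic_summary(self) -> KineticSummary:
        return KineticSummary.from_params(self.params)

    def predict(self) -> pd.DataFrame:
        """Fitted expected counts for every observation cell."""
        s = self.model._unit_predictions(self.rates)
        x0 = np.array([self.x0_groups[k] for k in self.model.group_keys])
        cells = self.model._cells[["condition", "t_pc", "site", "t_harvest"]].copy()
        cells["fitted"] = x0[self.model._cell_group] * s
        return cells

    # -- bootstrap -----------------------------------------------------
    def bootstrap_cis(
        self,
        n_boot: int = 200,
        seed: int = 0,
        settings: OptimizerSettings | None = None,
        level: float = 0.95,
        max_redraws: int = 10,
    ) -> dict[str, tuple[float, float]]:
        """Percentile bootstrap intervals for the rate/time parameters.

        Replicate mice are case-resampled within each (design, site, harvest
        time) cell; each resample is refitted (warm-started from the point
        estimate). Returns per-parameter (lower, upper) at ``level``.
        """
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        settings = settings or replace(self.settings, n_starts=3)
        rng = np.random.default_rng(seed)
        frame = self.model.dataset.frame
        groups = [idx.to_numpy() for _, idx in frame.groupby(
            ["design_id", "site", "t_harvest"], sort=True
        ).groups.items()]
        names = self.spec.rate_param_names()
        draws = {name: [] for name in names}
        for _ in range(n_boot):
            for _attempt in range(max_redraws):
                pieces = [g[rng.integers(0, len(g), size=len(g))] for g in groups]
                idx = np.concatenate(pieces)
                if len(idx) == len(frame):
                    break
            boot = TimeCourseDataset(frame.loc[idx].reset_index(drop=True))
            boot_model = MigrationModel(boot, self.spec)
            boot_res = boot_model.fit(
                replace(settings, seed=int(rng.integers(0, 2**31 - 1))),
                extra_starts=[self.theta],
            )
            for name in names:
                draws[name].append(boot_res.rates[name])
        lo_q, hi_q = 50.0 * (1.0 - level), 50.0 * (1.0 + level)
        cis = {
            name: (
                float(np.percentile(vals, lo_q)),
                float(np.percentile(vals, hi_q)),
            )
            for name, vals in draws.items()
        }
        self.bootstrap_intervals = cis
        return cis

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Photoconverted DC trafficking model",
            "=" * 52,
            f"model:       {self.spec.name}",
            f"n obs:       {self.n_obs}    free params: {self.n_params}",
            f"RSS (log):   {self.rss:.6g}",
            f"AIC:         {self.aic:.4f}",
            f"converged:   {self.converged}",
        ]
        if self.tau_weakly_identified:
            lines.append("note: tau weakly identified (no early dLN harvests)")
        lines.append("-" * 52)
        for name in self.spec.rate_param_names():
            entry = f"{name:14s} {self.rates[name]:12.6g} per h"
            if name in ("tau",):
                entry = f"{name:14s} {self.rates[name]:12.6g} h"
            if self.bootstrap_intervals and name in self.bootstrap_intervals:
                lo, hi = self.bootstrap_intervals[name]
                entry += f"   95% CI ({lo:.4g}, {hi:.4g})"
            lines.append(entry)
        ks = self.kinetic_summary()
        lines += [
            "-" * 52,
            f"dLN half-life (alum):    {ks.half_life_dln_alum:8.2f} h",
            f"dLN half-life (saline):  {ks.half_life_dln_saline:8.2f} h",
            f"skin mean residence:     {ks.mean_residence_skin_days:8.2f} d",
            f"transit time:            {ks.transit_time:8.2f} h",
            f"peak migration at:       {ks.peak_migration_time:8.2f} h "
            f"({ks.peak_fold_change:.1f}-fold)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "alum_rate_form": self.spec.alum_rate_form,
                "saline_rate_form": self.spec.saline_rate_form,
                "delta_shared": self.spec.delta_shared,
                "x0_policy": self.spec.x0_policy,
                "name": self.spec.name,
            },
            "rates": dict(self.rates),
            "x0": dict(self.x0_groups),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "tau_weakly_identified": self.tau_weakly_identified,
            "kinetic_summary": self.kinetic_summary().as_dict(),
            "bootstrap_intervals": self.bootstrap_intervals,
        }
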