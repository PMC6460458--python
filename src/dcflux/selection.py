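"""AIC model selection over the candidate trafficking-model family.

The default family spans the assumptions under comparison — whether the
alum migration hazard is constant or pulsed, and whether the dLN loss rate
is shared between conditions:

* M0: constant/constant, shared delta
* M1: constant/constant, per-condition delta
* M2: pulse-alum/constant, shared delta
* M3: pulse-alum/constant, per-condition delta

All members are fitted to the identical dataset and compared with the
least-squares AIC ``n ln(RSS/n) + 2 (k + 1)`` (the residual variance counts
as a parameter). When a simpler nested model sits within dAIC < 2 of the
minimum, it is reported as the winner on parsimony grounds, with both
models flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TimeCourseDataset
from .model import MigrationModel, MigrationResults, ModelSpec, OptimizerSettings

__all__ = [
    "aic",
    "aicc",
    "akaike_weights",
    "default_family",
    "compare_models",
    "SelectionTable",
]

logger = logging.getLogger(__name__)

#: dAIC below which a simpler nested model is preferred
PARSIMONY_DELTA = 2.0


def aic(rss: float, n_obs: int, k: int) -> float:
    """Least-squares AIC: ``n ln(RSS/n) + 2 (k + 1)``.

    The +1 counts the residual variance. A perfect fit (RSS = 0) is a
    degenerate case and returns ``-inf`` (logged).
    """
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if n_obs <= k + 1:
        raise ValueError(f"need n_obs > k + 1, got n_obs={n_obs}, k={k}")
    if rss == 0:
        logger.warning("RSS = 0: perfect fit, AIC is -inf")
        return -math.inf
    return n_obs * math.log(rss / n_obs) + 2.0 * (k + 1)


def aicc(rss: float, n_obs: int, k: int) -> float:
    """Small-sample corrected AIC (adds ``2 p (p+1) / (n - p - 1)``, p = k+1)."""
    p = k + 1
    base = aic(rss, n_obs, k)
    if n_obs - p - 1 <= 0:
        raise ValueError("AICc needs n_obs > k + 2")
    return base + 2.0 * p * (p + 1) / (n_obs - p - 1)


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)``."""
    aics = np.asarray(aics, dtype=float)
    if np.any(np.isneginf(aics)):  # perfect-fit sentinel dominates
        w = np.isneginf(aics).astype(float)
        return w / w.sum()
    d = aics - np.min(aics)
    w = np.exp(-0.5 * d)
    return w / w.sum()


def default_family() -> list[ModelSpec]:
    return [
        ModelSpec("constant", "constant", True, name="M0"),
        ModelSpec("constant", "constant", False, name="M1"),
        ModelSpec("pulse", "constant", True, name="M2"),
        ModelSpec("pulse", "constant", False, name="M3"),
    ]


@dataclass
class SelectionTable:
    """AIC comparison of a fitted model family, sorted by ascending AIC."""

    table: pd.DataFrame
    winner: str
    flags: list[str] = field(default_factory=list)
    results: dict[str, MigrationResults] = field(default_factory=dict, repr=False)

    def __getitem__(self, label: str) -> MigrationResults:
        return self.results[label]

    def summary(self) -> str:
        lines = ["Model selection (least-squares AIC)", "-" * 60]
        lines.append(
            self.table.to_string(
                index=False,
                formatters={
                    "rss": "{:.4f}".format,
                    "aic": "{:.2f}".format,
                    "delta_aic": "{:.2f}".format,
                    "akaike_weight": "{:.3f}".format,
                },
            )
        )
        lines.append(f"winner: {self.winner}")
        lines.extend(self.flags)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "winner": self.winner,
            "flags": list(self.flags),
        }


def _embed(source: MigrationResults, target: ModelSpec) -> np.ndarray:
    """Log-parameter start vector for ``target`` reproducing ``source``'s fit
    (tiny pulse amplitude where the source had none)."""
    r = source.rates
    mu0 = r["mu0"]
    values = {"mu0": mu0, "tau": r["tau"]}
    if "pulse" in (target.alum_rate_form, target.saline_rate_form):
        values["alpha"] = r.get("alpha", 1e-6 * mu0 * math.e / 24.0)
        values["m"] = r.get("m", 1.0 / 24.0)
    if target.delta_shared:
        values["delta"] = r.get(
            "delta", 0.5 * (r.get("delta_alum", 0.1) + r.get("delta_saline", 0.1))
        )
    else:
        shared = r.get("delta")
        values["delta_alum"] = r.get("delta_alum", shared)
        values["delta_saline"] = r.get("delta_saline", shared)
    if target.x0_policy == "from-recruitment-curve":
        for name in ("r0", "beta", "b"):
            values[name] = r[name]
    return np.log([values[name] for name in target.rate_param_names()])


def compare_models(
    dataset: TimeCourseDataset,
    family: list[ModelSpec] | None = None,
    settings: OptimizerSettings | None = None,
) -> SelectionTable:
    """Fit every family member to the identical dataset and rank by AIC.

    Members are fitted in order of increasing parameter count; each fit
    warm-starts from the optima of the already-fitted models nested within
    it, which guarantees RSS is non-increasing along nested chains. A member
    that fails to converge is excluded with a logged warning.
    """
    family = family or default_family()
    if not family:
        raise ValueError("family must be non-empty")
    settings = settings or OptimizerSettings()
    fitted: list[MigrationResults] = []
    order = sorted(range(len(family)), key=lambda i: len(family[i].rate_param_names()))
    for i in order:
        spec = family[i]
        model = MigrationModel(dataset, spec)
        extra = [
            _embed(prev, spec) for prev in fitted if prev.spec.is_nested_in(spec)
        ]
        res = model.fit(settings, extra_starts=extra)
        if not res.converged:
            logger.warning("model %s failed to converge; excluded", spec.name)
            continue
        fitted.append(res)
    if not fitted:
        raise RuntimeError("no model in the family converged")

    rows = [
        {
            "model": res.spec.name,
            "k": res.n_params,
            "rss": res.rss,
            "aic": res.aic,
        }
        for res in fitted
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    best_aic = table["aic"].iloc[0]
    table["delta_aic"] = np.where(
        np.isneginf(table["aic"].to_numpy()) & np.isneginf(best_aic),
        0.0,
        table["aic"] - best_aic,
    )
    table["akaike_weight"] = akaike_weights(table["aic"].to_numpy())

    flags: list[str] = []
    near = table[table["delta_aic"] < PARSIMONY_DELTA]
    winner = near.sort_values(["k", "aic"], kind="stable")["model"].iloc[0]
    if winner != table["model"].iloc[0]:
        flags.append(
            f"parsimony tie-break: {winner} (k={int(near.set_index('model')['k'][winner])}) "
            f"preferred over {table['model'].iloc[0]} at dAIC < {PARSIMONY_DELTA}"
        )
    return SelectionTable(
        table=table,
        winner=winner,
        flags=flags,
        results={res.spec.name: res for res in fitted},
    )
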