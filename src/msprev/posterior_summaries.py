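"""Reporting surface: prevalence tables, exceedance probabilities, map layers.

The headline product of the analysis is, per province j and outcome k, the
posterior distribution of the prevalence pP_jk together with the exceedance
probability against a national reference threshold c_k,

    P(pP_jk > c_k)  =  (1/G) sum_g 1{ pP_jk^(g) > c_k }

estimated as the fraction of retained MCMC draws strictly above the
threshold.  Provinces whose exceedance passes 0.95 are flagged as hot spots.
Chains are pooled after burn-in and thinning for all summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mcmc_engine import PosteriorDraws
from .survey_data import OUTCOMES, ProvinceAggregate

__all__ = [
    "ThresholdSet",
    "HOTSPOT_CUTOFF",
    "exceedance_probability",
    "summarize_provinces",
    "export_map_layers",
]

#: Exceedance level above which a province is reported as a hot spot.
HOTSPOT_CUTOFF = 0.95

#: National reference prevalences for (diabetes, obesity, hypertension,
#: elevated LDL): 9.4%, 25.1%, 26.9%, 22.7%.
DEFAULT_THRESHOLDS = (0.094, 0.251, 0.269, 0.227)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-outcome exceedance thresholds c_k, each in (0, 1)."""

    values: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if len(self.values) != len(OUTCOMES):
            raise ValueError(
                f"expected {len(OUTCOMES)} thresholds, got {len(self.values)}"
            )
        if not all(0.0 < c < 1.0 for c in self.values):
            raise ValueError("thresholds must lie strictly in (0, 1)")

    def __getitem__(self, outcome: str) -> float:
        return self.values[OUTCOMES.index(outcome)]


def exceedance_probability(samples: Sequence[float] | np.ndarray, c: float) -> float:
    """Fraction of posterior samples strictly greater than the threshold.

    Ties at c count as non-exceeding.  Monotone non-increasing in c.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("exceedance_probability requires at least one sample")
    return float(np.mean(samples > c))


def summarize_provinces(
    draws: PosteriorDraws,
    thresholds: ThresholdSet | Sequence[float] | None = None,
    aggregates: Sequence[ProvinceAggregate] | None = None,
) -> pd.DataFrame:
    """Per-province, per-outcome posterior summary table.

    Columns: posterior mean, SD, median, 2.5% and 97.5% quantiles of the
    province prevalence, the exceedance probability at the outcome's
    threshold, the hot-spot flag (exceedance >= 0.95), posterior means of
    the spatial (u) and uncorrelated (v) province effects, and — when the
    aggregates are supplied — the crude estimate y/n and the sampled flag.
    Unsampled provinces are flagged: their estimates are driven by the
    spatial prior and covariates, not by local data.
    """
    if thresholds is None:
        thresholds = ThresholdSet()
    elif not isinstance(thresholds, ThresholdSet):
        thresholds = ThresholdSet(tuple(float(c) for c in thresholds))

    C, G, J, K = draws.p_prov.shape
    rows = []
    for j in range(J):
        agg = aggregates[j] if aggregates is not None else None
        for k, outcome in enumerate(OUTCOMES):
            s = draws.p_prov[:, :, j, k].ravel()  # pooled chains
            q025, med, q975 = np.quantile(s, (0.025, 0.5, 0.975))
            exc = exceedance_probability(s, thresholds.values[k])
            row = {
                "province_id": j + 1,
                "outcome": outcome,
                "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                "median": float(med),
                "q2.5": float(q025),
                "q97.5": float(q975),
                "threshold": thresholds.values[k],
                "exceedance": exc,
                "hotspot": exc >= HOTSPOT_CUTOFF,
                "u_mean": float(draws.up[:, :, j, k].mean()),
                "v_mean": float(draws.vp[:, :, j, k].mean()),
            }
            if agg is not None:
                crude = agg.crude_prevalence[k]
                row["crude"] = float(crude) if np.isfinite(crude) else np.nan
                row["sampled"] = bool(agg.sampled_flag)
            rows.append(row)
    return pd.DataFrame(rows)


def export_map_layers(
    summary: pd.DataFrame,
    path: str | Path,
    geometry: str | Path | None = None,
    id_property: str = "province_id",
) -> None:
    """Write a map-ready file joining the summary to province geometry.

    With ``geometry`` a GeoJSON FeatureCollection keyed by ``id_property``
    (1-based province ids), a GeoJSON file is written whose feature
    properties carry, per outcome, the posterior mean, exceedance and the
    u/v effect means.  Without geometry a wide delimited table is written
    instead.  Raises when the summary and geometry province ids disagree.
    """
    wide = summary.pivot(
        index="province_id", columns="outcome",
        values=[c for c in ("mean", "exceedance", "u_mean", "v_mean")
                if c in summary.columns],
    )
    wide.columns = [f"{stat}_{outcome}" for stat, outcome in wide.columns]
    wide = wide.reset_index()

    if geometry is None:
        wide.to_csv(path, index=False)
        return

    with open(geometry) as fh:
        gj = json.load(fh)
    feats = {int(f["properties"][id_property]): f for f in gj["features"]}
    summary_ids = set(wide["province_id"].astype(int))
    mismatch = sorted(summary_ids ^ set(feats))
    if mismatch:
        raise ValueError(f"province ids mismatch between summary and geometry: {mismatch}")
    out_feats = []
    for _, row in wide.iterrows():
        f = feats[int(row["province_id"])]
        props = dict(f["properties"])
        for col in wide.columns:
            if col != "province_id":
                props[col] = float(row[col])
        out_feats.append({"type": "Feature", "geometry": f["geometry"],
                          "properties": props})
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": out_feats})
    )
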