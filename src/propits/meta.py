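"""Random-effects meta-analysis of per-site proportion differences.

Site-level ITS estimates are pooled with the DerSimonian–Laird
moment estimator of the between-site variance tau².  Pools are produced
per country and overall, mirroring a forest-plot layout of sites, country
subtotals and a grand total.  Confidence intervals are Wald (normal);
a Knapp–Hartung small-sample adjustment is available but off by default,
matching the plain random-effects presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class MetaInput:
    """One study (site) entering a pool."""

    site_id: str
    country: str
    estimate: float  # proportion difference, pp/month
    se: float  # standard error (bootstrap SD of the difference)

    def __post_init__(self) -> None:
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValidationError(f"site {self.site_id}: se must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics."""

    scope: str  # "overall" or a country label
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float  # percentage
    k: int
    tau2_flagged: bool = False  # True when k=1 and tau2 is undefined

    def as_row(self) -> dict:
        return {
            "scope": self.scope,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "Q": self.Q,
            "I2": self.I2,
            "k": self.k,
            "tau2_flagged": self.tau2_flagged,
        }


def dersimonian_laird(
    inputs: list[MetaInput],
    *,
    scope: str = "overall",
    alpha: float = 0.05,
    knapp_hartung: bool = False,
) -> MetaResult:
    """DerSimonian–Laird random-effects pool of site estimates.

    Fixed-effect weights w_i = 1/se_i² give Cochran's Q; the moment
    estimator tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) then yields
    random-effects weights w*_i = 1/(se_i² + tau²), the pooled estimate
    Σw*θ/Σw*, and SE 1/sqrt(Σw*).  I² = max(0, 100·(Q−(k−1))/Q).

    With a single study the estimate and its own Wald CI are returned and
    tau² is reported as 0 with a flag.
    """
    k = len(inputs)
    if k == 0:
        raise ValidationError("meta-analysis requires at least one study")
    theta = np.array([s.estimate for s in inputs], dtype=float)
    var = np.array([s.se**2 for s in inputs], dtype=float)

    if k == 1:
        se = float(np.sqrt(var[0]))
        z = stats.norm.ppf(1 - alpha / 2)
        return MetaResult(
            scope=scope,
            estimate=float(theta[0]),
            se=se,
            ci_low=float(theta[0] - z * se),
            ci_high=float(theta[0] + z * se),
            tau2=0.0,
            Q=0.0,
            I2=0.0,
            k=1,
            tau2_flagged=True,
        )

    w = 1.0 / var
    theta_fe = float((w * theta).sum() / w.sum())
    Q = float((w * (theta - theta_fe) ** 2).sum())
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (Q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (var + tau2)
    pooled = float((w_star * theta).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    I2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0

    if knapp_hartung:
        # Variance rescaled by the weighted residual mean square; t reference.
        q_star = float((w_star * (theta - pooled) ** 2).sum() / (k - 1))
        se = se * np.sqrt(max(q_star, 1.0))
        crit = stats.t.ppf(1 - alpha / 2, df=k - 1)
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
    return MetaResult(
        scope=scope,
        estimate=pooled,
        se=se,
        ci_low=float(pooled - crit * se),
        ci_high=float(pooled + crit * se),
        tau2=float(tau2),
        Q=Q,
        I2=float(I2),
        k=k,
    )


def pool_hierarchy(
    inputs: list[MetaInput], *, alpha: float = 0.05, knapp_hartung: bool = False
) -> list[MetaResult]:
    """Country-level pools followed by the overall pool.

    Countries are pooled in the sorted order of their labels; each pool is
    an independent DerSimonian–Laird fit over the sites it contains.
    """
    if not inputs:
        raise ValidationError("no studies to pool")
    results: list[MetaResult] = []
    for country in sorted({s.country for s in inputs}):
        sub = [s for s in inputs if s.country == country]
        results.append(
            dersimonian_laird(sub, scope=country, alpha=alpha, knapp_hartung=knapp_hartung)
        )
    results.append(
        dersimonian_laird(inputs, scope="overall", alpha=alpha, knapp_hartung=knapp_hartung)
    )
    return results


def meta_frame(results: list[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def forest_table(inputs: list[MetaInput], pools: list[MetaResult]) -> pd.DataFrame:
    """Forest-plot-style table: site rows, country pools, overall pool.

    Site weight percentages are random-effects weights from the overall
    pool, normalized to 100.
    """
    overall = next(r for r in pools if r.scope == "overall")
    w_star = np.array([1.0 / (s.se**2 + overall.tau2) for s in inputs])
    weights = 100.0 * w_star / w_star.sum()
    z = stats.norm.ppf(0.975)
    rows = [
        {
            "label": s.site_id,
            "scope": "site",
            "estimate": s.estimate,
            "ci_low": s.estimate - z * s.se,
            "ci_high": s.estimate + z * s.se,
            "weight_pct": float(wt),
        }
        for s, wt in zip(inputs, weights)
    ]
    for pool in pools:
        rows.append(
            {
                "label": pool.scope,
                "scope": "country" if pool.scope != "overall" else "overall",
                "estimate": pool.estimate,
                "ci_low": pool.ci_low,
                "ci_high": pool.ci_high,
                "weight_pct": np.nan,
            }
        )
    return pd.DataFrame(rows)
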