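"""Agreement statistics between benchmark GEBV and indirect predictions.

Per scenario and replicate: Pearson and Spearman correlations, the
intercept and slope of the regression of GEBV on IP (ideal 0 and 1), the
root-mean-square difference, the mean standardized bias
``(mean IP − mean GEBV)/σa`` and the variance ratio ``var(GEBV)/var(IP)``.
Statistics are computed within replicate and then averaged, reported as
mean ± SE across replicates; 95% CIs use the Fisher z transform for
correlations and the OLS t intervals for the regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .indirect import IpResult

__all__ = ["EvalReport", "ReplicateSummary", "evaluate", "aggregate_replicates",
           "render_tables", "STATISTICS"]

STATISTICS = ("pearson", "spearman", "b0", "b1", "rmse", "std_bias", "var_ratio")


@dataclass
class EvalReport:
    """Scenario-level agreement between GEBV and IP (one replicate)."""

    n: int
    pearson: float
    spearman: float
    b0: float
    b1: float
    rmse: float
    std_bias: float
    var_ratio: float
    mean_gebv: float
    mean_ip: float
    ci95: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {s: getattr(self, s) for s in STATISTICS}


def _fisher_ci(r: float, n: int, level: float = 0.95):
    r = min(max(r, -0.999999), 0.999999)
    if n <= 3:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


def evaluate(gebv: np.ndarray, ip, sigma2_a: float = 0.25) -> EvalReport:
    """All agreement statistics of one scenario in one replicate.

    ``gebv`` are the benchmark predictions of the candidates; ``ip`` an
    :class:`~ipsim.indirect.IpResult` or a plain vector aligned to it.
    """
    ip_vec = ip.ip if isinstance(ip, IpResult) else np.asarray(ip, float)
    gebv = np.asarray(gebv, float)
    if gebv.size != ip_vec.size:
        raise ValueError("GEBV and IP lengths differ")
    n = gebv.size
    if n < 3:
        raise ValueError("need at least 3 animals to evaluate")
    if np.var(ip_vec) == 0:
        raise ValueError("zero-variance IP")
    pear = stats.pearsonr(gebv, ip_vec)
    spear = stats.spearmanr(gebv, ip_vec)
    ols = sm.OLS(gebv, sm.add_constant(ip_vec)).fit()
    b0, b1 = float(ols.params[0]), float(ols.params[1])
    ci_reg = ols.conf_int(alpha=0.05)
    rmse = float(np.sqrt(np.mean((gebv - ip_vec) ** 2)))
    std_bias = float((ip_vec.mean() - gebv.mean()) / np.sqrt(sigma2_a))
    var_ratio = float(np.var(gebv, ddof=1) / np.var(ip_vec, ddof=1))
    return EvalReport(
        n=n,
        pearson=float(pear.statistic),
        spearman=float(spear.statistic),
        b0=b0,
        b1=b1,
        rmse=rmse,
        std_bias=std_bias,
        var_ratio=var_ratio,
        mean_gebv=float(gebv.mean()),
        mean_ip=float(ip_vec.mean()),
        ci95={
            "pearson": _fisher_ci(float(pear.statistic), n),
            "spearman": _fisher_ci(float(spear.statistic), n),
            "b0": (float(ci_reg[0, 0]), float(ci_reg[0, 1])),
            "b1": (float(ci_reg[1, 0]), float(ci_reg[1, 1])),
        },
    )


@dataclass
class ReplicateSummary:
    """Cross-replicate mean ± SE (and averaged CIs) per scenario/statistic."""

    table: pd.DataFrame          # scenario, statistic, mean, se, ci_low, ci_high
    n_replicates: int
    scenarios: tuple

    def stat(self, scenario: str, statistic: str, col: str = "mean") -> float:
        t = self.table
        row = t[(t.scenario == scenario) & (t.statistic == statistic)]
        return float(row[col].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def aggregate_replicates(reports: dict) -> ReplicateSummary:
    """Aggregate ``{scenario: [EvalReport, ...]}`` across replicates.

    SE = sd/sqrt(n); with a single replicate SE (and CI averaging of
    nothing further) is reported as NaN-free mean with SE = NaN.
    """
    rows = []
    scenarios = tuple(reports.keys())
    n_rep = None
    for scen, reps in reports.items():
        if len(reps) == 0:
            raise ValueError(f"no replicates for scenario {scen}")
        n_rep = len(reps)
        for s in STATISTICS:
            vals = np.array([getattr(r, s) for r in reps], float)
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            cis = [r.ci95.get(s) for r in reps if r.ci95.get(s) is not None]
            ci_lo = float(np.mean([c[0] for c in cis])) if cis else np.nan
            ci_hi = float(np.mean([c[1] for c in cis])) if cis else np.nan
            rows.append({"scenario": scen, "statistic": s, "mean": float(vals.mean()),
                         "se": se, "ci_low": ci_lo, "ci_high": ci_hi})
    return ReplicateSummary(pd.DataFrame(rows), n_rep, scenarios)


def render_tables(summary: ReplicateSummary):
    """Scenario-by-statistic tables: correlations/regression and error/bias.

    Returns ``(accuracy_df, error_df, text)`` where the first mirrors a
    correlation + regression layout and the second RMSE / standardized
    bias / variance ratio, scenario rows in fixed order (correct, then
    ascending error rates).
    """
    order = [s for s in ("correct", "E05", "E10", "E20") if s in summary.scenarios]
    order += [s for s in summary.scenarios if s not in order]

    def fmt(scen, stat):
        m = summary.stat(scen, stat)
        se = summary.stat(scen, stat, "se")
        return f"{m:.2f} ± {se:.2f}" if np.isfinite(se) else f"{m:.2f}"

    acc = pd.DataFrame({
        "scenario": order,
        **{s: [summary.stat(sc, s) for sc in order]
           for s in ("pearson", "spearman", "b0", "b1")},
    })
    err = pd.DataFrame({
        "scenario": order,
        **{s: [summary.stat(sc, s) for sc in order]
           for s in ("rmse", "std_bias", "var_ratio")},
    })
    lines = ["scenario  pearson      spearman     b0           b1",]
    for sc in order:
        lines.append(
            f"{sc:<9} " + "  ".join(fmt(sc, s) for s in ("pearson", "spearman", "b0", "b1"))
        )
    lines.append("")
    lines.append("scenario  rmse         std_bias     var_ratio")
    for sc in order:
        lines.append(
            f"{sc:<9} " + "  ".join(fmt(sc, s) for s in ("rmse", "std_bias", "var_ratio"))
        )
    return acc, err, "\n".join(lines)


def predictions_long(gebv: np.ndarray, ips: dict, animal_ids, replicate: int) -> pd.DataFrame:
    """Long-format (id, replicate, scenario, gebv, ip) export for plotting."""
    frames = []
    for scen, res in ips.items():
        frames.append(pd.DataFrame({
            "id": np.asarray(animal_ids),
            "replicate": replicate,
            "scenario": scen,
            "gebv": np.asarray(gebv, float),
            "ip": np.asarray(res.ip if isinstance(res, IpResult) else res, float),
        }))
    return pd.concat(frames, ignore_index=True)
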