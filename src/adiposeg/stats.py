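"""Cross-modality agreement statistics and report generation.

Agreement between paired CT and MR measurements is summarised by the
Pearson correlation, the Bland–Altman bias (mean of MR − CT
differences) with limits of agreement LOA = bias ± 1.96 × SD of the
differences, a Lilliefors-corrected Kolmogorov–Smirnov normality test
per vector, and a two-tailed paired t-test.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .fat_quant import QuantResult

MEASURES = ("outer", "inner", "sat", "vat")
Z_95 = 1.96


@dataclass
class AgreementResult:
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    loa_ci_halfwidth: float
    t_statistic: float
    t_pvalue: float
    ks_pvalue_x: float
    ks_pvalue_y: float
    n: int
    measure: str = ""


def compare_modalities(x, y) -> AgreementResult:
    """Agreement of paired measurements; bias is mean(y − x), i.e. MR − CT
    when x holds the CT values.

    Degenerate inputs follow fixed conventions: zero-variance differences
    give t_pvalue = 1 (the modalities are indistinguishable); zero
    variance in x or y makes the Pearson correlation undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("agreement statistics need n >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - Z_95 * sd
    loa_high = bias + Z_95 * sd
    # SE of a limit of agreement ~ sqrt(3/n) * SD (Bland & Altman)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    loa_ci_halfwidth = tcrit * sd * np.sqrt(3.0 / n)

    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = float(sps.pearsonr(x, y).statistic)

    if sd == 0:
        t_stat, t_p = 0.0, 1.0
    else:
        t = sps.ttest_rel(y, x)
        t_stat, t_p = float(t.statistic), float(t.pvalue)

    def _ks(v: np.ndarray) -> float:
        if v.std(ddof=1) == 0:
            return 1.0
        if v.size < 4:  # Lilliefors table needs n >= 4
            return float(sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue)
        return float(lilliefors(v, dist="norm")[1])

    return AgreementResult(
        pearson_r=r,
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        loa_ci_halfwidth=loa_ci_halfwidth,
        t_statistic=t_stat,
        t_pvalue=t_p,
        ks_pvalue_x=_ks(x),
        ks_pvalue_y=_ks(y),
        n=n,
    )


def _pair_results(
    results_ct: list[QuantResult], results_mr: list[QuantResult]
) -> tuple[list[str], dict[str, np.ndarray], dict[str, np.ndarray]]:
    ct_by_id = {r.source_id: r for r in results_ct}
    mr_by_id = {r.source_id: r for r in results_mr}
    ids = sorted(set(ct_by_id) & set(mr_by_id))
    unmatched = sorted(set(ct_by_id) ^ set(mr_by_id))
    if unmatched:
        raise ValueError(f"unmatched source ids: {', '.join(unmatched)}")
    if not ids:
        raise ValueError("no paired results")

    def columns(by_id):
        return {
            "outer": np.array([by_id[i].outer_area_cm2 for i in ids]),
            "inner": np.array([by_id[i].inner_area_cm2 for i in ids]),
            "sat": np.array([by_id[i].sat_area_cm2 for i in ids]),
            "vat": np.array([by_id[i].vat_area_cm2 for i in ids]),
        }

    return ids, columns(ct_by_id), columns(mr_by_id)


def agreement_report(
    results_ct: list[QuantResult],
    results_mr: list[QuantResult],
    out_dir: str | Path,
) -> dict[str, AgreementResult]:
    """Per-measure scatter and Bland–Altman plots plus a stats CSV.

    Results are paired by source_id; unmatched ids raise with the list
    of offenders.  Writes agreement.csv and one PNG per measure into
    out_dir and returns the AgreementResult per measure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _, ct_cols, mr_cols = _pair_results(results_ct, results_mr)

    rows: dict[str, AgreementResult] = {}
    for measure in MEASURES:
        x, y = ct_cols[measure], mr_cols[measure]
        res = compare_modalities(x, y)
        res.measure = measure
        rows[measure] = res

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(x, y, s=18)
        lims = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax1.plot(lims, lims, "k--", lw=0.8)
        ax1.set_xlabel(f"CT {measure} (cm$^2$)")
        ax1.set_ylabel(f"MR {measure} (cm$^2$)")
        ax1.set_title(f"r = {res.pearson_r:.3f}")

        mean_xy = (x + y) / 2.0
        ax2.scatter(mean_xy, y - x, s=18)
        ax2.axhline(res.bias, color="C1", label=f"bias {res.bias:+.2f}")
        ax2.axhline(res.loa_low, color="C1", ls="--")
        ax2.axhline(res.loa_high, color="C1", ls="--")
        ax2.set_xlabel(f"mean of CT and MR {measure} (cm$^2$)")
        ax2.set_ylabel("MR − CT (cm$^2$)")
        ax2.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"agreement_{measure}.png", dpi=110)
        plt.close(fig)

    with open(out / "agreement.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        header = list(asdict(next(iter(rows.values()))).keys())
        writer.writerow(header)
        for measure in MEASURES:
            writer.writerow(asdict(rows[measure]).values())
    return rows
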