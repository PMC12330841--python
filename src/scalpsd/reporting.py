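"""Normality-gated summary tables and channel plots.

Each fitted-parameter metric is summarised as mean ± StD when the
Shapiro–Wilk test does not reject normality at alpha = 0.05, otherwise
as median [IQR] (IQR reported as a single width).  Outliers are never
excluded.  Scalp-vs-ECoG pulse duration is additionally compared with a
paired two-sided test — Student's t when the paired differences pass
Shapiro–Wilk, Wilcoxon signed-rank otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SHAPIRO_ALPHA = 0.05

#: metric name -> extractor over a ComparisonRecord
_METRICS = {
    "peak_uV_scalp": lambda r: r.scalp_fit.A,
    "peak_uV_ecog": lambda r: r.ecog_fit.A,
    "amplitude_ratio": lambda r: r.ratio,
    "fwhm_s_scalp": lambda r: r.scalp_fit.fwhm,
    "fwhm_s_ecog": lambda r: r.ecog_fit.fwhm,
    "fwhm_ratio": lambda r: r.fwhm_ratio,
    "peak_dt_s": lambda r: r.peak_dt,
    "cod": lambda r: r.cod,
}


@dataclass
class SummaryTable:
    table: pd.DataFrame  # one row per metric
    paired_fwhm_test: dict  # test name, statistic, p
    n: int

    def __str__(self) -> str:
        lines = [self.table.to_string(index=False)]
        t = self.paired_fwhm_test
        if t:
            lines.append(
                f"scalp vs ECoG FWHM: {t['test']} p = {t['p']:.2e}"
            )
        return "\n".join(lines)


def _summarise_one(name: str, x: np.ndarray) -> dict:
    x = x[np.isfinite(x)]
    n = x.size
    if n == 0:
        return dict(metric=name, n=0, display="-")
    if np.ptp(x) == 0:
        # constant data: Shapiro-Wilk undefined, dispersion is zero
        return dict(
            metric=name, n=n, central=float(x[0]), dispersion=0.0,
            form="mean±StD", normality_p=np.nan,
            display=f"{x[0]:.4g} ± 0 (constant)",
        )
    p = stats.shapiro(x).pvalue if n >= 3 else np.nan
    if n < 3 or p >= SHAPIRO_ALPHA:
        c, d = float(np.mean(x)), float(np.std(x, ddof=1))
        form, disp = "mean±StD", f"{c:.4g} ± {d:.3g}"
    else:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        c, d = float(med), float(q3 - q1)
        form, disp = "median[IQR]", f"{c:.4g} [{d:.3g}]"
    return dict(
        metric=name, n=n, central=c, dispersion=d, form=form,
        normality_p=float(p) if np.isfinite(p) else np.nan, display=disp,
    )


def summarize(records: list, extents: list | None = None) -> SummaryTable:
    """Build the per-metric summary over usable comparison records.

    ``extents`` (optional, parallel to ``records``) adds half-max area
    and equivalent diameter rows.  Requires at least 3 usable records
    for the normality-gated forms; below that a raw listing is all that
    is meaningful and a ValueError is raised.
    """
    usable = [r for r in records if r.usable]
    if len(usable) < 3:
        raise ValueError("need at least 3 usable records to summarise")
    rows = [
        _summarise_one(name, np.array([f(r) for r in usable], dtype=float))
        for name, f in _METRICS.items()
    ]
    if extents is not None:
        pairs = [
            (r, e) for r, e in zip(records, extents) if r.usable and e is not None
        ]
        areas = np.array([e.area for _, e in pairs], dtype=float)
        diams = np.array([e.diameter for _, e in pairs], dtype=float)
        rows.append(_summarise_one("area_cm2", areas))
        rows.append(_summarise_one("diameter_cm", diams))

    s = np.array([r.scalp_fit.fwhm for r in usable])
    e = np.array([r.ecog_fit.fwhm for r in usable])
    diff = s - e
    if np.ptp(diff) == 0:
        paired = dict(test="constant differences", statistic=np.nan, p=np.nan)
    elif stats.shapiro(diff).pvalue >= SHAPIRO_ALPHA:
        t = stats.ttest_rel(s, e)
        paired = dict(test="paired t-test", statistic=float(t.statistic),
                      p=float(t.pvalue))
    else:
        w = stats.wilcoxon(s, e)
        paired = dict(test="Wilcoxon signed-rank", statistic=float(w.statistic),
                      p=float(w.pvalue))
    return SummaryTable(table=pd.DataFrame(rows), paired_fwhm_test=paired,
                        n=len(usable))


def channel_plot(
    epoch,
    path,
    full_scale_uv: float = 680.0,
    negative_up: bool = True,
    event_times_s=None,
    title: str | None = None,
):
    """Stacked per-channel traces of a detrended epoch.

    Dead channels are omitted (noted in the corner); each trace is
    offset by one full-scale unit, labels run along the right edge; the
    scalp convention plots negative up.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    live = epoch.live_labels()
    if not live:
        raise ValueError("no live channels to plot")
    t = epoch.times()
    sign = -1.0 if negative_up else 1.0
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(live) + 1.5))
    for k, lab in enumerate(live):
        v = epoch.detrended[epoch.labels.index(lab)]
        offset = -k * full_scale_uv
        ax.plot(t / 60.0, sign * v + offset, lw=0.6, color="k")
        ax.annotate(lab, (t[-1] / 60.0, offset), xytext=(4, 0),
                    textcoords="offset points", fontsize=7, va="center")
    if event_times_s is not None:
        for et in event_times_s:
            ax.axvline(et / 60.0, color="r", lw=0.5, alpha=0.6)
    omitted = sorted(set(epoch.labels) - set(live))
    if omitted:
        ax.set_title(
            (title or "") + f"  (dead channels omitted: {', '.join(omitted)})",
            fontsize=8,
        )
    elif title:
        ax.set_title(title, fontsize=9)
    ax.set_xlabel("time (min)")
    ax.set_yticks([])
    ax.set_xlim(t[0] / 60.0, t[-1] / 60.0)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
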