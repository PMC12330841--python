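"""Six-parameter DC-shift model and scalp/ECoG similarity statistics.

A spreading-depolarization DC-shift is modelled as a negative Gaussian
pulse riding on a slow quadratic baseline,

    v(t) = A exp(-(t - t0)^2 / (2 sigma^2)) + c0 + c1 t + c2 t^2,

fitted per channel by bounded nonlinear least squares to the 8-second
bin means of an epoch wide enough to contain the whole shift plus stable
baseline (default 4 min; 12 min for slow or cluttered events).  Derived
quantities are the full width at half maximum, FWHM = 2.355 sigma, and
the pulse frequency 1/FWHM.

Scalp and invasive (ECoG) recordings of the same event are compared by
removing each side's fitted baseline, scaling the scalp series by the
inverse of the fitted amplitude ratio, and computing the square of the
Pearson correlation between the two series — the Coefficient of
Determination (CoD).  CoD > 0.80 is taken as structural similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

FWHM_PER_SIGMA = 2.355
COD_SIMILARITY_THRESHOLD = 0.80
MIN_FIT_BINS = 12


@dataclass
class DCShiftFit:
    """Fitted pulse + baseline parameters for one channel.

    Amplitude keeps its sign: spreading depolarizations are negative
    deflections, so ``A < 0`` for a genuine event.
    """

    A: float  # peak amplitude, µV
    t0: float  # peak time, s
    sigma: float  # Gaussian width, s
    c0: float  # baseline offset, µV
    c1: float  # linear drift, µV/s
    c2: float  # quadratic drift, µV/s²
    rel_param_err: np.ndarray  # per-parameter |std err / value|
    converged: bool
    flags: tuple[str, ...] = ()
    epoch_width: float = 240.0
    channel: str | None = None

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma

    @property
    def frequency(self) -> float:
        return 1.0 / self.fwhm

    @property
    def params(self) -> np.ndarray:
        return np.array([self.A, self.t0, self.sigma, self.c0, self.c1, self.c2])

    def baseline(self, t: np.ndarray) -> np.ndarray:
        return self.c0 + self.c1 * t + self.c2 * t * t

    def pulse(self, t: np.ndarray) -> np.ndarray:
        return self.A * np.exp(-((t - self.t0) ** 2) / (2 * self.sigma**2))

    def model(self, t: np.ndarray) -> np.ndarray:
        return self.pulse(t) + self.baseline(t)


@dataclass
class ComparisonRecord:
    """Scalp-vs-ECoG pairing of one DC-shift event."""

    event_id: str
    scalp_fit: DCShiftFit
    ecog_fit: DCShiftFit
    ratio: float  # scalp A / ECoG A
    fwhm_ratio: float  # scalp FWHM / ECoG FWHM
    peak_dt: float  # scalp t0 - ECoG t0, s; positive = scalp delayed
    cod: float
    usable: bool = True

    @property
    def similar(self) -> bool:
        return self.usable and self.cod > COD_SIMILARITY_THRESHOLD


def _model(t, A, t0, sigma, c0, c1, c2):
    return A * np.exp(-((t - t0) ** 2) / (2 * sigma**2)) + c0 + c1 * t + c2 * t * t


def fit_gaussian_quadratic(
    times: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray | None = None,
    epoch_width: float | None = None,
    channel: str | None = None,
) -> DCShiftFit:
    """Fit the Gaussian-plus-quadratic-baseline model by least squares.

    Parameters
    ----------
    times, values
        Bin-centre times (s) and bin-mean voltages (µV).
    mask
        Optional boolean array, True for bins to exclude (manual artifact
        removal); NaN values are excluded automatically.
    epoch_width
        Recorded on the result for bookkeeping; defaults to the time span.

    Notes
    -----
    The fit is initialised from the extremum of the linearly detrended
    series (amplitude and peak time) with sigma at 1/4 of the window, and
    falls back to a small multi-start over sigma if the optimizer fails.
    Failure is reported via ``converged=False`` and ``flags``, never
    raised.  A flat input (no resolvable pulse) is flagged ``"no shift"``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    t, v = times[keep], values[keep]
    if t.size < MIN_FIT_BINS:
        raise ValueError(
            f"need at least {MIN_FIT_BINS} unmasked bins, got {t.size}"
        )
    span = float(t[-1] - t[0])
    width = float(epoch_width) if epoch_width is not None else span

    # Fit in window-centred time for conditioning (a quadratic in raw
    # seconds is badly scaled hours into a recording), then map the
    # baseline coefficients back to absolute time.
    t_ref = 0.5 * (t[0] + t[-1])
    tc = t - t_ref

    # Global initialisation by profiling: for fixed (t0, sigma) the model
    # is linear in (A, c0, c1, c2), so scan a (t0, sigma) grid with
    # linear least squares and keep the best few basins.
    quad = np.column_stack([np.ones_like(tc), tc, tc * tc])
    candidates = []
    for t0g in tc:
        for sg in np.geomspace(span / 20.0, span, 10):
            g = np.exp(-((tc - t0g) ** 2) / (2.0 * sg * sg))
            G = np.column_stack([g, quad])
            coef, *_ = np.linalg.lstsq(G, v, rcond=None)
            ss = float(np.sum((G @ coef - v) ** 2))
            candidates.append((ss, [coef[0], t0g, sg, *coef[1:]]))
    candidates.sort(key=lambda c: c[0])

    bounds = (
        [-np.inf, tc[0] - span, span / 200.0, -np.inf, -np.inf, -np.inf],
        [np.inf, tc[-1] + span, 2.0 * span, np.inf, np.inf, np.inf],
    )
    best = None
    for ss0, p0 in candidates[:3]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    _model, tc, v, p0=p0, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((_model(tc, *popt) - v) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
        if best[2] <= ss0 + 1e-12:
            break  # polish already beat every remaining start's bound

    if best is None:
        return DCShiftFit(
            A=np.nan, t0=np.nan, sigma=np.nan, c0=np.nan, c1=np.nan, c2=np.nan,
            rel_param_err=np.full(6, np.nan), converged=False,
            flags=("optimizer failed",), epoch_width=width, channel=channel,
        )

    popt, pcov, _ = best
    if popt[2] < 0:  # sigma enters squared; normalise sign
        popt[2] = -popt[2]
    # map centred-time parameters to absolute time:
    # t0 += t_ref; c0,c1 pick up the baseline shift terms
    jac = np.eye(6)
    jac[3, 4], jac[3, 5] = -t_ref, t_ref**2
    jac[4, 5] = -2.0 * t_ref
    pcov = jac @ pcov @ jac.T
    d0, d1, d2 = popt[3], popt[4], popt[5]
    popt = np.array(
        [
            popt[0],
            popt[1] + t_ref,
            popt[2],
            d0 - d1 * t_ref + d2 * t_ref**2,
            d1 - 2.0 * d2 * t_ref,
            d2,
        ]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        perr = np.sqrt(np.diag(pcov))
        rel = np.abs(perr / np.where(popt == 0, np.nan, popt))
    # absence call: amplitude within the post-fit noise floor, or a
    # "pulse" too wide to resolve inside the window (baseline-degenerate)
    res = v - _model(t, *popt)
    noise_post = 1.4826 * np.median(np.abs(res - np.median(res)))
    flags: list[str] = []
    if (
        abs(popt[0]) <= 4.0 * max(noise_post, 1e-12)
        or popt[2] >= span  # wider than the window: baseline-degenerate
        or not (t[0] <= popt[1] <= t[-1])  # peak outside the window
    ):
        flags.append("no shift")
    return DCShiftFit(
        A=float(popt[0]), t0=float(popt[1]), sigma=float(popt[2]),
        c0=float(popt[3]), c1=float(popt[4]), c2=float(popt[5]),
        rel_param_err=rel, converged=True, flags=tuple(flags),
        epoch_width=width, channel=channel,
    )


def derive_metrics(fit: DCShiftFit) -> tuple[float, float]:
    """Return (FWHM, frequency) = (2.355 sigma, 1/FWHM)."""
    if not fit.sigma > 0:
        raise ValueError("sigma must be positive")
    fwhm = FWHM_PER_SIGMA * fit.sigma
    return fwhm, 1.0 / fwhm


def select_peak_channel(fits: dict[str, DCShiftFit]) -> str:
    """Channel whose fitted pulse deviates most from zero.

    Fits flagged ``"no shift"`` (amplitude at the noise floor, or a
    baseline-degenerate pulse wider than the window) are not candidates
    unless no channel resolved a pulse.  Ties on |A| are broken by the
    smaller amplitude relative error, then by label order.
    """
    usable = {
        lab: f
        for lab, f in fits.items()
        if f.converged and np.isfinite(f.A) and "no shift" not in f.flags
    }
    if not usable:
        # no resolved pulse anywhere: fall back to the raw amplitude rule
        usable = {
            lab: f for lab, f in fits.items()
            if f.converged and np.isfinite(f.A)
        }
    if not usable:
        raise ValueError("no converged fits")

    def key(lab):
        f = usable[lab]
        rel_a = f.rel_param_err[0]
        return (-abs(f.A), rel_a if np.isfinite(rel_a) else np.inf, lab)

    return min(usable, key=key)


def scale_and_cod(
    scalp: np.ndarray, ecog: np.ndarray, ratio: float | None = None
) -> tuple[float, float]:
    """Scale a baseline-subtracted scalp series onto the ECoG series and
    return ``(ratio, CoD)``.

    Both inputs must already have their fitted baselines removed and be
    sampled on the same bins.  If ``ratio`` (scalp amplitude / ECoG
    amplitude, from the fits) is not given, it is estimated from the
    signed extrema of the two series.  The CoD is the square of the
    Pearson correlation of the scaled series — and is therefore
    invariant to the scaling itself; the scaling matters for plotting
    and residual diagnostics, the correlation for the similarity call.
    """
    scalp = np.asarray(scalp, dtype=float)
    ecog = np.asarray(ecog, dtype=float)
    if scalp.shape != ecog.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(scalp) & np.isfinite(ecog)
    scalp, ecog = scalp[ok], ecog[ok]
    if scalp.std() == 0 or ecog.std() == 0:
        raise ValueError("zero-variance series: CoD undefined")
    if ratio is None:
        s_ext = scalp[np.argmax(np.abs(scalp))]
        e_ext = ecog[np.argmax(np.abs(ecog))]
        ratio = s_ext / e_ext
    r = stats.pearsonr(scalp / ratio, ecog).statistic
    return float(ratio), float(r * r)


def compare_event(
    scalp_times: np.ndarray,
    scalp_values: np.ndarray,
    ecog_times: np.ndarray,
    ecog_values: np.ndarray,
    event_id: str = "event",
    scalp_mask: np.ndarray | None = None,
    ecog_mask: np.ndarray | None = None,
    use_raw_extrema: bool = False,
) -> ComparisonRecord:
    """Fit both sides of one event and fill a ComparisonRecord.

    ``*_values`` may be 1-D (a single, already-selected peak channel) or
    a dict ``{label: series}`` of candidate channels, in which case the
    per-side peak channel (largest |A|) is selected after fitting all of
    them.  ``peak_dt`` is scalp t0 minus ECoG t0, positive when the
    scalp peak lags.  With ``use_raw_extrema`` the amplitude ratio is
    taken from the raw baseline-subtracted extrema instead of the fitted
    amplitudes.
    """

    def fit_side(times, values, mask):
        if isinstance(values, dict):
            fits = {
                lab: fit_gaussian_quadratic(times, v, mask, channel=lab)
                for lab, v in values.items()
            }
            lab = select_peak_channel(fits)
            return fits[lab], np.asarray(values[lab], dtype=float)
        f = fit_gaussian_quadratic(times, values, mask)
        return f, np.asarray(values, dtype=float)

    scalp_fit, scalp_series = fit_side(scalp_times, scalp_values, scalp_mask)
    ecog_fit, ecog_series = fit_side(ecog_times, ecog_values, ecog_mask)

    if not (scalp_fit.converged and ecog_fit.converged):
        return ComparisonRecord(
            event_id=event_id, scalp_fit=scalp_fit, ecog_fit=ecog_fit,
            ratio=np.nan, fwhm_ratio=np.nan, peak_dt=np.nan, cod=np.nan,
            usable=False,
        )

    scalp_flat = scalp_series - scalp_fit.baseline(np.asarray(scalp_times, float))
    ecog_flat = ecog_series - ecog_fit.baseline(np.asarray(ecog_times, float))
    n = min(scalp_flat.size, ecog_flat.size)
    fitted_ratio = scalp_fit.A / ecog_fit.A
    ratio_arg = None if use_raw_extrema else fitted_ratio
    ratio, cod = scale_and_cod(scalp_flat[:n], ecog_flat[:n], ratio=ratio_arg)
    return ComparisonRecord(
        event_id=event_id,
        scalp_fit=scalp_fit,
        ecog_fit=ecog_fit,
        ratio=float(ratio),
        fwhm_ratio=scalp_fit.fwhm / ecog_fit.fwhm,
        peak_dt=scalp_fit.t0 - ecog_fit.t0,
        cod=cod,
    )


def records_table(records: list[ComparisonRecord]):
    """ComparisonRecords as a DataFrame, one row per event."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            dict(
                event_id=r.event_id,
                scalp_channel=r.scalp_fit.channel,
                ecog_channel=r.ecog_fit.channel,
                peak_uV_scalp=r.scalp_fit.A,
                peak_uV_ecog=r.ecog_fit.A,
                amplitude_ratio=r.ratio,
                fwhm_s_scalp=r.scalp_fit.fwhm if r.scalp_fit.converged else np.nan,
                fwhm_s_ecog=r.ecog_fit.fwhm if r.ecog_fit.converged else np.nan,
                fwhm_ratio=r.fwhm_ratio,
                peak_dt_s=r.peak_dt,
                cod=r.cod,
                similar=r.similar,
                usable=r.usable,
            )
        )
    return pd.DataFrame(rows)
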