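"""Acceptability screening of scalp DC-shift events.

A candidate scalp DC-shift is accepted for comparison with an invasively
coded spreading depolarization when:

1. it appears with varying amplitude in more than one — but not all —
   live channels (membership: |A| at least 30% of the peak |A|);
2. its peak amplitude lies between −230 and −1200 µV, the range implied
   by plausible scalp/brain attenuation ratios applied to cortical
   DC-shift amplitudes;
3. its half-max spatial extent is about 4 cm across (threshold:
   equivalent diameter ≥ 3.5 cm);
4. (when history exists) it recurs at the same location — the peak
   channel lies within one electrode spacing of a previously accepted
   event's peak channel inside a look-back window (default 12 h).

Criteria 1–3 are always required; criterion 4 is reported
``not-applicable`` when no prior accepted events are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dcshift import DCShiftFit
from .field import ExtentResult
from .layouts import ElectrodeLayout

SCREENING_DEFAULTS = dict(
    member_frac=0.30,          # channel counts as "showing the shift"
    amp_lo_uv=-1200.0,
    amp_hi_uv=-230.0,
    min_diameter_cm=3.5,
    lookback_s=12 * 3600.0,
    same_location_spacings=1.0,
)


@dataclass
class ScreeningResult:
    event_id: str
    c1_multichannel: bool
    c2_amplitude: bool
    c3_extent: bool | None  # None = indeterminate (no extent available)
    c4_repetition: str  # "pass" | "fail" | "not-applicable"
    details: str = ""
    peak_channel: str | None = None
    peak_time: float | None = None

    @property
    def accepted(self) -> bool:
        if self.c3_extent is None:
            return False  # deferred
        return (
            self.c1_multichannel
            and self.c2_amplitude
            and self.c3_extent
            and self.c4_repetition in ("pass", "not-applicable")
        )


def screen_event(
    event_id: str,
    fits: dict[str, DCShiftFit],
    extent: ExtentResult | None,
    layout: ElectrodeLayout,
    history: list[ScreeningResult] | None = None,
    config: dict | None = None,
) -> ScreeningResult:
    """Apply acceptability criteria 1–4 to one event.

    ``fits`` maps channel label to its DCShiftFit for the event epoch;
    ``history`` holds previously *accepted* events (most recent last)
    for the repetition criterion.
    """
    cfg = dict(SCREENING_DEFAULTS)
    if config:
        cfg.update(config)
    live = [l for l in layout.live_labels if l in fits]
    conv = {l: f for l, f in fits.items() if l in live and f.converged}
    if not conv:
        raise ValueError("no converged fits among live channels")

    # Channel amplitude is taken as the range of the fitted pulse over
    # the fit window rather than the raw A parameter: on channels with
    # no pulse the optimizer can trade a very wide Gaussian against the
    # quadratic baseline, producing a large A whose in-window excursion
    # is nonetheless tiny.
    peak0 = min(conv, key=lambda l: (-abs(conv[l].A), l))
    width = conv[peak0].epoch_width
    grid = np.linspace(
        conv[peak0].t0 - width / 2, conv[peak0].t0 + width / 2, 97
    )
    eff = {l: float(np.ptp(f.pulse(grid))) for l, f in conv.items()}
    peak_lab = min(conv, key=lambda l: (-eff[l], l))
    peak_fit = conv[peak_lab]
    peak_A = peak_fit.A

    n_members = sum(
        1 for l in conv if eff[l] >= cfg["member_frac"] * eff[peak_lab]
    )
    c1 = 2 <= n_members < len(live)
    c2 = cfg["amp_lo_uv"] <= peak_A <= cfg["amp_hi_uv"]
    c3 = None if extent is None else extent.diameter >= cfg["min_diameter_cm"]

    if not history:
        c4 = "not-applicable"
    else:
        px, py = layout.position_of(peak_lab)
        tol = cfg["same_location_spacings"] * layout.spacing + 1e-9
        c4 = "fail"
        for prior in history:
            if prior.peak_channel is None or prior.peak_time is None:
                continue
            if (
                peak_fit.t0 - prior.peak_time > cfg["lookback_s"]
                or peak_fit.t0 < prior.peak_time
            ):
                continue
            qx, qy = layout.position_of(prior.peak_channel)
            if np.hypot(px - qx, py - qy) <= tol:
                c4 = "pass"
                break

    details = (
        f"peak {peak_lab} A={peak_A:.1f}µV, {n_members}/{len(live)} member channels"
    )
    if extent is not None:
        details += f", diameter {extent.diameter:.2f}cm"
    else:
        details += ", extent missing (c3 indeterminate, event deferred)"
    return ScreeningResult(
        event_id=event_id,
        c1_multichannel=c1,
        c2_amplitude=c2,
        c3_extent=c3,
        c4_repetition=c4,
        details=details,
        peak_channel=peak_lab,
        peak_time=peak_fit.t0,
    )


def screening_table(results: list[ScreeningResult]):
    """Per-event screening booleans as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                event_id=r.event_id,
                c1_multichannel=r.c1_multichannel,
                c2_amplitude=r.c2_amplitude,
                c3_extent=r.c3_extent,
                c4_repetition=r.c4_repetition,
                accepted=r.accepted,
                peak_channel=r.peak_channel,
                details=r.details,
            )
            for r in results
        ]
    )
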